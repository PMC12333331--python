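"""Generate the plain-text PBE0/def2-SVP butadiene fixture bundles shipped
under ``src/dressedtddft/data``.

Requires the optional live engine (pyscf).  Run from the repository root:

    python scripts/make_fixtures.py [--basis def2-svp] [--out src/dressedtddft/data]

Each geometry comes from the parametric s-trans-butadiene builder; per
geometry a 2x2 Ag-subspace bundle (HOMO-1->LUMO, HOMO->LUMO+1 mixed with
HOMO^2->LUMO^2) is extracted, plus a 1x1 HOMO->LUMO (Bu) bundle at the
equilibrium-region point.  Everything is written through the documented
file-backend layout, so re-reading the fixtures exercises the same code
path users rely on.
"""

import argparse
import os
import sys
import time

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from dressedtddft import build_butadiene, live_backend, save_file_backend

SCAN_BLA = [-0.10, -0.08, -0.06, -0.04, -0.03, -0.02, -0.01,
            0.00, 0.02, 0.04, 0.07, 0.10, 0.13]
EQUILIBRIUM_BLA = 0.13


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--basis", default="def2-svp")
    parser.add_argument("--functional", default="PBE0")
    parser.add_argument("--out", default=os.path.join(
        os.path.dirname(__file__), "..", "src", "dressedtddft", "data",
        "butadiene_pbe0_def2svp"))
    args = parser.parse_args()

    os.makedirs(args.out, exist_ok=True)
    for bla in SCAN_BLA:
        t0 = time.time()
        geom = build_butadiene(bla)
        bundle = live_backend(
            geom, functional=args.functional, basis=args.basis,
            singles=(("HOMO-1", "LUMO"), ("HOMO", "LUMO+1")),
            double=("HOMO", "LUMO"),
        )
        bundle.provenance["bla"] = bla
        bundle.provenance["geometry_source"] = "parametric builder"
        slot = os.path.join(args.out, f"ag_bla_{bla:+.4f}")
        save_file_backend(slot, bundle)
        print(f"ag bla={bla:+.4f}: E_gs={bundle.energy_ground:.8f} "
              f"({time.time() - t0:.0f} s)", flush=True)

    t0 = time.time()
    geom = build_butadiene(EQUILIBRIUM_BLA)
    bundle = live_backend(
        geom, functional=args.functional, basis=args.basis,
        singles=(("HOMO", "LUMO"),), double=("HOMO", "LUMO"),
    )
    bundle.provenance["bla"] = EQUILIBRIUM_BLA
    bundle.provenance["geometry_source"] = "parametric builder"
    save_file_backend(os.path.join(args.out, f"bu_bla_{EQUILIBRIUM_BLA:+.4f}"), bundle)
    print(f"bu bla={EQUILIBRIUM_BLA:+.4f} done ({time.time() - t0:.0f} s)", flush=True)


if __name__ == "__main__":
    main()
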