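"""Optional full reproduction of the published 1Bu/2Ag crossing scan.

Requires the live engine (pyscf) and, for quantitative comparison with the
published crossing coordinate, the externally published BLA-parametrized
butadiene geometry set supplied as XYZ files (one per geometry).  Without
``--geometry-dir`` the parametric builder is used as a stand-in.

    python scripts/reproduce_bla_scan.py --basis cc-pvtz \
        [--geometry-dir path/to/xyz] [--out-dir scan_out]

Warning: at cc-pVTZ this is an hours-scale calculation.
"""

import argparse
import glob
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from dressedtddft import (
    DressingSpec,
    Geometry,
    StateRequest,
    build_butadiene,
    butadiene_bla,
    live_backend,
    locate_crossing,
    scan_pes,
)

DEFAULT_BLA = [-0.10, -0.08, -0.06, -0.04, -0.03, -0.02, -0.01,
               0.00, 0.02, 0.04, 0.07, 0.10, 0.13]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--basis", default="cc-pvtz")
    parser.add_argument("--functional", default="PBE0")
    parser.add_argument("--variant", default="a", choices=["S", "a"])
    parser.add_argument("--geometry-dir", default=None,
                        help="directory of XYZ files; BLA recomputed from "
                             "coordinates (carbons in chain order)")
    parser.add_argument("--out-dir", default="scan_out")
    args = parser.parse_args()

    if args.geometry_dir:
        geometries = {}
        for path in sorted(glob.glob(os.path.join(args.geometry_dir, "*.xyz"))):
            geom = Geometry.read_xyz(path)
            geometries[butadiene_bla(geom)] = geom
    else:
        print("note: using parametric-builder geometries (stand-in); supply "
              "--geometry-dir for quantitative comparison", file=sys.stderr)
        geometries = {bla: build_butadiene(bla) for bla in DEFAULT_BLA}

    bundles = {}
    for bla, geom in sorted(geometries.items()):
        print(f"running {args.functional}/{args.basis} at bla={bla:+.4f}",
              flush=True)
        bundles[bla] = live_backend(
            geom, functional=args.functional, basis=args.basis,
            singles=(("HOMO-1", "LUMO"), ("HOMO", "LUMO+1")),
            double=("HOMO", "LUMO"),
        )

    states = [
        StateRequest("2Ag", 0, DressingSpec(variant=args.variant)),
        StateRequest("1Bu", "adiabatic_s1", DressingSpec(variant="none")),
    ]
    result = scan_pes(bundles, states, max_iter=100, track_characters=False)
    for bla in locate_crossing(result, "1Bu", "2Ag"):
        result.crossings.append((("1Bu", "2Ag"), bla))
    os.makedirs(args.out_dir, exist_ok=True)
    result.write_csv(os.path.join(args.out_dir, "scan.csv"))
    result.write_json(os.path.join(args.out_dir, "scan.json"))
    print("crossings:", result.crossings)


if __name__ == "__main__":
    main()
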