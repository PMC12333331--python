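"""Bond-length-alternation (BLA) scans: parametric s-trans-butadiene
geometries, per-geometry dressed/adiabatic solves, and crossing location.

The BLA coordinate is the average single-bond length minus the average
double-bond length of the conjugated backbone.  The parametric builder is
a documented stand-in: quantitative comparison with published crossings
requires the externally published geometry set, which users can supply as
XYZ files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dressing import DressingSpec
from .solver import ExcitedState, oscillator_strength, solve_state
from .units import HARTREE_TO_EV

__all__ = [
    "Geometry",
    "ButadieneTemplate",
    "PESPoint",
    "ScanResult",
    "StateRequest",
    "build_butadiene",
    "butadiene_bla",
    "scan_pes",
    "locate_crossing",
]


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class Geometry:
    """A molecular structure in angstrom."""

    symbols: Tuple[str, ...]
    coords: np.ndarray
    comment: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(len(self.symbols), 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))

    def to_xyz(self) -> str:
        lines = [str(len(self.symbols)), self.comment]
        for s, (x, y, z) in zip(self.symbols, self.coords):
            lines.append(f"{s} {x:.10f} {y:.10f} {z:.10f}")
        return "\n".join(lines) + "\n"

    def write_xyz(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_xyz())

    @classmethod
    def from_xyz(cls, text: str) -> "Geometry":
        lines = text.strip().splitlines()
        natoms = int(lines[0].split()[0])
        comment = lines[1] if len(lines) > 1 else ""
        symbols, coords = [], []
        for line in lines[2 : 2 + natoms]:
            parts = line.split()
            symbols.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        return cls(tuple(symbols), np.asarray(coords), comment)

    @classmethod
    def read_xyz(cls, path) -> "Geometry":
        with open(path) as fh:
            return cls.from_xyz(fh.read())


@dataclass(frozen=True)
class ButadieneTemplate:
    """Fixed internal parameters of the planar s-trans (C2h) builder.

    ``cc_mean`` is the mean CC bond length; single and double CC bonds are
    set to ``cc_mean +/- bla/2``.  The remaining constants are documented
    defaults, not fitted to any published geometry set.
    """

    cc_mean: float = 1.405
    ch_inner: float = 1.090
    ch_terminal: float = 1.086
    angle_ccc_deg: float = 123.6
    angle_terminal_deg: float = 121.0


def build_butadiene(bla: float, template: ButadieneTemplate = ButadieneTemplate()) -> Geometry:
    """Planar s-trans butadiene with the requested BLA (angstrom).

    The backbone is C1=C2-C3=C4 with the inversion center at the midpoint
    of the central single bond; each terminal carbon carries two hydrogens
    and each inner carbon one, all in plane.
    """
    if abs(bla) > 0.5:
        raise ScanError(f"unphysical bla={bla} (|bla| must be <= 0.5 angstrom)")
    r_single = template.cc_mean + 0.5 * bla
    r_double = template.cc_mean - 0.5 * bla
    theta = math.radians(template.angle_ccc_deg)

    c2 = np.array([0.0, 0.0, 0.0])
    c3 = np.array([r_single, 0.0, 0.0])
    c1 = c2 + r_double * np.array([math.cos(theta), math.sin(theta), 0.0])
    center = 0.5 * (c2 + c3)
    c4 = 2.0 * center - c1

    def unit(v):
        return v / np.linalg.norm(v)

    def rot(v, deg):
        a = math.radians(deg)
        c, s = math.cos(a), math.sin(a)
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])

    # inner hydrogens bisect the exterior CCC angle
    h2 = c2 - template.ch_inner * unit(unit(c1 - c2) + unit(c3 - c2))
    h4_inner = 2.0 * center - h2
    # terminal hydrogens at +/- angle_terminal from the C1->C2 bond direction
    u12 = unit(c2 - c1)
    ha = c1 + template.ch_terminal * rot(u12, template.angle_terminal_deg)
    hb = c1 + template.ch_terminal * rot(u12, -template.angle_terminal_deg)
    ha4 = 2.0 * center - ha
    hb4 = 2.0 * center - hb

    symbols = ("C", "C", "C", "C", "H", "H", "H", "H", "H", "H")
    coords = np.vstack([c1, c2, c3, c4, ha, hb, h2, h4_inner, ha4, hb4])
    geom = Geometry(symbols, coords, comment=f"s-trans-butadiene bla={bla:.6f}")
    check = butadiene_bla(geom)
    if abs(check - bla) > 1e-10:
        raise ScanError(f"builder self-check failed: requested {bla}, got {check}")
    return geom


def butadiene_bla(geometry: Geometry) -> float:
    """Recompute the BLA from coordinates (carbons in C1..C4 file order)."""
    carbons = [k for k, s in enumerate(geometry.symbols) if s.upper() == "C"]
    if len(carbons) != 4:
        raise ScanError("expected exactly four carbons")
    c = geometry.coords[carbons]
    single = np.linalg.norm(c[2] - c[1])
    doubles = [np.linalg.norm(c[1] - c[0]), np.linalg.norm(c[3] - c[2])]
    return float(single - np.mean(doubles))


@dataclass(frozen=True)
class StateRequest:
    """One state to track along the scan: which adiabatic root to start
    from and which dressing to apply to it.

    ``target`` is an index into the subspace's adiabatic spectrum, or the
    sentinel ``"adiabatic_s1"`` for the full-space ATDDFT state of the
    double's constituent single (e.g. the bright HOMO->LUMO state, which
    need not belong to the dressed subspace)."""

    label: str
    target: object
    spec: DressingSpec


@dataclass
class PESPoint:
    bla: float
    energies: Dict[str, float]  # eV, relative to the Franck-Condon ground state
    weights: Dict[str, float]
    converged: Dict[str, bool]
    oscillator_strengths: Dict[str, float] = field(default_factory=dict)
    error: Optional[str] = None


@dataclass
class ScanResult:
    points: List[PESPoint]
    crossings: List[Tuple[Tuple[str, str], float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"bla": p.bla}
            for label, e in p.energies.items():
                row[f"E_{label}_eV"] = e
            for label, w in p.weights.items():
                row[f"weight_{label}"] = w
            for label, f in p.oscillator_strengths.items():
                row[f"f_{label}"] = f
            for label, c in p.converged.items():
                row[f"converged_{label}"] = c
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path) -> None:
        doc = {
            "points": [
                {
                    "bla": p.bla,
                    "energies_eV": p.energies,
                    "weights": p.weights,
                    "oscillator_strengths": p.oscillator_strengths,
                    "converged": p.converged,
                    "error": p.error,
                }
                for p in self.points
            ],
            "crossings": [
                {"states": list(pair), "bla": bla} for pair, bla in self.crossings
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def scan_pes(
    bundles: Mapping[float, "BackendBundle"],
    states: Sequence[StateRequest],
    tol: float = 1e-6,
    max_iter: int = 50,
    fc_bla: Optional[float] = None,
    track_characters: bool = True,
) -> ScanResult:
    """Solve the requested states at every geometry of a BLA scan.

    ``bundles`` maps the BLA coordinate to a ready
    :class:`~dressedtddft.backends.BackendBundle`.  Energies are reported
    relative to the Franck-Condon ground state (the point whose BLA is
    ``fc_bla``, by default the one with the lowest ground-state energy);
    when ground-state energies are absent, bare excitation energies are
    reported instead.  State identity is tracked across adjacent
    geometries by eigenvector-overlap continuity.  Per-point failures are
    recorded and the scan continues.
    """
    if not bundles:
        raise ScanError("empty geometry list")
    blas = sorted(bundles)
    gs = {b: bundles[b].energy_ground for b in blas}
    have_gs = all(v is not None for v in gs.values())
    if have_gs:
        if fc_bla is None:
            fc_bla = min(blas, key=lambda b: gs[b])
        elif fc_bla not in gs:
            raise ScanError(f"fc_bla={fc_bla} is not one of the scan points")
        e_fc = gs[fc_bla]

    points: List[PESPoint] = []
    solved: List[Dict[str, Optional[ExcitedState]]] = []
    for bla in blas:
        bundle = bundles[bla]
        energies, weights, conv, strengths = {}, {}, {}, {}
        solved_here: Dict[str, Optional[ExcitedState]] = {}
        err = None
        for req in states:
            try:
                if req.target == "adiabatic_s1":
                    omega_ev = bundle.subspace.omega_adia_s1 * HARTREE_TO_EV
                    if have_gs:
                        omega_ev += (gs[bla] - e_fc) * HARTREE_TO_EV
                    energies[req.label] = float(omega_ev)
                    weights[req.label] = 1.0
                    conv[req.label] = True
                    solved_here[req.label] = None
                    continue
                state = solve_state(
                    bundle.subspace, req.spec, target=req.target,
                    tol=tol, max_iter=max_iter, label=req.label,
                )
                omega_ev = state.omega * HARTREE_TO_EV
                if have_gs:
                    omega_ev += (gs[bla] - e_fc) * HARTREE_TO_EV
                energies[req.label] = float(omega_ev)
                weights[req.label] = float(state.norm_weight)
                conv[req.label] = bool(state.converged)
                if bundle.subspace.dipoles is not None:
                    strengths[req.label] = oscillator_strength(
                        state, None, bundle.subspace
                    )
                solved_here[req.label] = state
            except Exception as exc:  # record, keep scanning
                conv[req.label] = False
                err = f"{req.label}: {exc}"
                solved_here[req.label] = None
        points.append(
            PESPoint(bla=float(bla), energies=energies, weights=weights,
                     converged=conv, oscillator_strengths=strengths, error=err)
        )
        solved.append(solved_here)

    if track_characters:
        _relabel_by_continuity(points, solved, [req.label for req in states])
    return ScanResult(points=points)


def _relabel_by_continuity(points, solved, labels) -> None:
    """Swap labels between adjacent points when eigenvector overlap says the
    characters crossed.  Only meaningful for same-dimension subspaces."""
    for k in range(1, len(points)):
        prev, cur = solved[k - 1], solved[k]
        usable = [
            lab for lab in labels
            if prev.get(lab) is not None and cur.get(lab) is not None
            and prev[lab].g.shape == cur[lab].g.shape
        ]
        if len(usable) < 2:
            continue
        overlap = np.zeros((len(usable), len(usable)))
        for i, la in enumerate(usable):
            for j, lb in enumerate(usable):
                ga, gb = prev[la].g, cur[lb].g
                overlap[i, j] = abs(
                    ga @ gb / (np.linalg.norm(ga) * np.linalg.norm(gb))
                )
        # greedy assignment; swap stored quantities when labels permute
        perm = {}
        free = set(range(len(usable)))
        for i in np.argsort(-overlap.max(axis=1)):
            j = max(free, key=lambda jj: overlap[i, jj])
            perm[usable[i]] = usable[j]
            free.remove(j)
        if all(a == b for a, b in perm.items()):
            continue
        pt = points[k]
        for container in (pt.energies, pt.weights, pt.converged,
                          pt.oscillator_strengths):
            before = dict(container)
            for a, b in perm.items():
                if b in before:
                    container[a] = before[b]
        cur_before = dict(cur)
        for a, b in perm.items():
            cur[a] = cur_before[b]


def locate_crossing(result: ScanResult, state_a: str, state_b: str) -> List[float]:
    """BLA estimates of every sign change of E_a - E_b, by linear
    interpolation between the bracketing scan points.  No sign change
    returns an empty list (not an error)."""
    pts = [
        p for p in sorted(result.points, key=lambda p: p.bla)
        if state_a in p.energies and state_b in p.energies
        and np.isfinite(p.energies[state_a]) and np.isfinite(p.energies[state_b])
    ]
    crossings = []
    for left, right in zip(pts, pts[1:]):
        g0 = left.energies[state_a] - left.energies[state_b]
        g1 = right.energies[state_a] - right.energies[state_b]
        if g0 == 0.0:
            crossings.append(left.bla)
        elif g0 * g1 < 0:
            frac = g0 / (g0 - g1)
            crossings.append(left.bla + frac * (right.bla - left.bla))
    if pts and pts[-1].energies[state_a] == pts[-1].energies[state_b]:
        crossings.append(pts[-1].bla)
    return crossings
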