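"""Unit-cell matching for polymorph identification from 3D electron diffraction.

3D ED yields lattice parameters (a, b, c, alpha, beta, gamma) from
sub-micrometer crystals.  Because the same lattice admits infinitely
many primitive cells, measured and reference cells are first brought to
their Niggli reduced form (the canonical reduced cell, computed with
gemmi's Krivy-Gruber implementation) and then compared parameter by
parameter with separate relative-length and absolute-angle tolerances.

Matching on reduced cells alone is weaker evidence than matching that
also uses systematic absences from reflection intensities; callers
should treat a match as a lattice-level identification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "CellReferenceEntry",
    "CellMatchResult",
    "niggli_reduce",
    "cell_distance",
    "match_cell",
    "load_cell_library",
    "default_cell_library",
]

DEFAULT_LEN_TOL = 0.02   # relative, on each reduced axis
DEFAULT_ANG_TOL = 1.5    # degrees, on each reduced angle


@dataclass(frozen=True)
class UnitCell:
    """Six lattice parameters; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    esds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0 < v < 180:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        if self.volume() <= 0 or not math.isfinite(self.volume()):
            raise ValueError("degenerate cell: metric tensor not positive definite")

    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles())
        arg = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)


@dataclass(frozen=True)
class CellReferenceEntry:
    polymorph_id: str
    refcode: str
    cell: UnitCell
    synthetic: bool = False


@dataclass(frozen=True)
class CellMatchResult:
    best_entry: CellReferenceEntry
    distance_score: float
    within_tolerance: bool
    ranked_alternatives: tuple[tuple[str, float], ...]  # (polymorph_id, score), ascending


def niggli_reduce(cell: UnitCell) -> UnitCell:
    """Canonical Niggli reduced cell (a <= b <= c, standard angle conventions).

    Volume is preserved; the operation is idempotent and removes the
    dependence on axis labeling and centering choices of the input.
    """
    gc = gemmi.UnitCell(*cell.parameters())
    gv = gemmi.GruberVector(gc, None, True)
    gv.niggli_reduce()
    a, b, c, alpha, beta, gamma = gv.cell_parameters()
    reduced = UnitCell(a, b, c, alpha, beta, gamma)
    if abs(reduced.volume() - cell.volume()) > 1e-8 * cell.volume():
        raise ValueError("reduction failed to preserve cell volume")
    return reduced


def cell_distance(
    x: UnitCell,
    y: UnitCell,
    len_tol: float = DEFAULT_LEN_TOL,
    ang_tol: float = DEFAULT_ANG_TOL,
) -> float:
    """Dimensionless dissimilarity of two cells after Niggli reduction.

    score = max over the six parameters of
        |relative length difference| / len_tol   (a, b, c)
        |angle difference in degrees| / ang_tol  (alpha, beta, gamma)

    so score <= 1 exactly when every parameter agrees within tolerance.
    Relative length differences are taken against the smaller of the two
    values, which keeps the score symmetric and makes a length off by
    exactly ``len_tol`` score exactly 1.
    """
    rx, ry = niggli_reduce(x), niggli_reduce(y)
    score = 0.0
    for lx, ly in zip(rx.lengths(), ry.lengths()):
        score = max(score, abs(lx - ly) / min(lx, ly) / len_tol)
    for ax, ay in zip(rx.angles(), ry.angles()):
        score = max(score, abs(ax - ay) / ang_tol)
    return score


def match_cell(
    cell: UnitCell,
    refs: Sequence[CellReferenceEntry],
    len_tol: float = DEFAULT_LEN_TOL,
    ang_tol: float = DEFAULT_ANG_TOL,
) -> CellMatchResult:
    """Rank reference cells by distance to a measured cell.

    The best-scoring entry is a match when its score is <= 1 (all
    parameters within tolerance); otherwise the full ranking is still
    returned with ``within_tolerance=False``.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("reference library is empty")
    scored = sorted(
        ((cell_distance(cell, r.cell, len_tol, ang_tol), r) for r in refs),
        key=lambda t: (t[0], t[1].polymorph_id),
    )
    best_score, best = scored[0]
    return CellMatchResult(
        best_entry=best,
        distance_score=best_score,
        within_tolerance=best_score <= 1.0,
        ranked_alternatives=tuple((r.polymorph_id, s) for s, r in scored),
    )


def load_cell_library(path: str | Path) -> tuple[CellReferenceEntry, ...]:
    """Read a cell reference library from JSON ({"entries": [...]})."""
    doc = json.loads(Path(path).read_text())
    records = doc["entries"] if isinstance(doc, dict) else doc
    entries = []
    seen = set()
    for rec in records:
        key = (rec["polymorph_id"], rec.get("refcode", ""))
        if key in seen:
            raise ValueError(f"duplicate library entry {key}")
        seen.add(key)
        entries.append(
            CellReferenceEntry(
                polymorph_id=rec["polymorph_id"],
                refcode=rec.get("refcode", ""),
                cell=UnitCell(
                    rec["a"], rec["b"], rec["c"],
                    rec["alpha"], rec["beta"], rec["gamma"],
                ),
                synthetic=bool(rec.get("synthetic", False)),
            )
        )
    return tuple(entries)


def default_cell_library() -> tuple[CellReferenceEntry, ...]:
    """Shipped template library: the measured ON cell plus synthetic placeholders."""
    return load_cell_library(Path(__file__).parent / "data" / "roy_cells_template.json")
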