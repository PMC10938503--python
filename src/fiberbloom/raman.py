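"""Polymorph assignment from nitrile-stretch Raman positions, color and habit.

ROY (5-methyl-2-[(2-nitrophenyl)amino]thiophene-3-carbonitrile) owes its
name to its red/orange/yellow polymorphs, which are distinguishable by
the wavenumber of the nitrile C#N stretching band (nu_CN, roughly
2205-2240 cm^-1).  Several polymorphs share nu_CN positions to within
the measurement tolerance, so classification proceeds in stages:

1. candidate polymorphs whose reference nu_CN lies within a shift
   tolerance of the measured position (3.0 cm^-1 by default),
2. filtering by crystal color, then by habit, when those attributes are
   recorded for the observation,
3. among survivors, the smallest |shift residual| wins; an exact
   residual tie is reported as ambiguous rather than silently guessed.

Entries flagged tentative in the reference library (the RPL red-plate
form, whose literature signature is a 2210/2215 cm^-1 doublet) propagate
a tentative confidence to any crystal they are assigned to.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RamanReferenceEntry",
    "CrystalObservation",
    "AssignmentResult",
    "CompositionSummary",
    "PeakPick",
    "NITRILE_WINDOW",
    "default_library",
    "load_library",
    "find_nitrile_peak",
    "assign_polymorph",
    "summarize_composition",
]

#: wavenumber window searched for the nitrile stretch, cm^-1
NITRILE_WINDOW = (2180.0, 2260.0)
#: plausible range for any nitrile reference position, cm^-1
_NITRILE_RANGE = (2150.0, 2260.0)
DEFAULT_SHIFT_TOL = 3.0


@dataclass(frozen=True)
class RamanReferenceEntry:
    """Signature of one polymorph: nu_CN position(s), color and typical habit."""

    polymorph_id: str
    nu_cn_cm1: tuple[float, ...]
    color: str
    habit: str = "any"
    tentative: bool = False

    def __post_init__(self) -> None:
        pos = tuple(float(p) for p in (
            self.nu_cn_cm1 if isinstance(self.nu_cn_cm1, (tuple, list)) else (self.nu_cn_cm1,)
        ))
        object.__setattr__(self, "nu_cn_cm1", pos)
        lo, hi = _NITRILE_RANGE
        for p in pos:
            if not lo <= p <= hi:
                raise ValueError(
                    f"{self.polymorph_id}: nu_CN {p} outside nitrile window {_NITRILE_RANGE}"
                )

    def residual(self, measured: float) -> float:
        """Smallest absolute offset between measurement and any reference peak."""
        return min(abs(measured - p) for p in self.nu_cn_cm1)


@dataclass(frozen=True)
class CrystalObservation:
    """One measured crystal: peak position plus optional visual attributes."""

    nu_cn_cm1: float
    peak_fwhm_cm1: float | None = None
    color: str | None = None
    habit: str | None = None
    source_id: str = ""


@dataclass(frozen=True)
class AssignmentResult:
    polymorph_id: str | None
    confidence: str  # unambiguous | disambiguated_by_attributes | tentative | ambiguous | unassigned
    shift_residual_cm1: float | None
    candidates: tuple[str, ...] = ()

    @property
    def assigned(self) -> bool:
        return self.polymorph_id is not None and self.confidence not in ("ambiguous", "unassigned")


@dataclass(frozen=True)
class CompositionSummary:
    counts: dict[str, int]
    total_n: int
    n_assigned: int
    n_ambiguous: int
    n_unassigned: int
    fractions: dict[str, float]


def default_library() -> tuple[RamanReferenceEntry, ...]:
    """Reference signatures for the ROY polymorphs relevant on fiber surfaces.

    The six forms observed on polyethylene fibers (Y, YN, ON, OP, R,
    RPL) plus the three yellow forms (Y04, YT04, Y19) that share nu_CN
    positions with ON/YN and must be excluded by color and habit.
    """
    path = Path(__file__).parent / "data" / "roy_raman.json"
    return load_library(path)


def load_library(path: str | Path) -> tuple[RamanReferenceEntry, ...]:
    """Read a reference library from JSON (list of entry objects)."""
    records = json.loads(Path(path).read_text())
    entries = []
    seen = set()
    for rec in records:
        pid = rec["polymorph_id"]
        if pid in seen:
            raise ValueError(f"duplicate polymorph_id {pid!r} in library")
        seen.add(pid)
        pos = rec["nu_cn_cm1"]
        if isinstance(pos, str):
            pos = [float(x) for x in pos.split(";")]
        elif isinstance(pos, (int, float)):
            pos = [pos]
        entries.append(
            RamanReferenceEntry(
                polymorph_id=pid,
                nu_cn_cm1=tuple(pos),
                color=rec["color"],
                habit=rec.get("habit", "any"),
                tentative=bool(rec.get("tentative", False)),
            )
        )
    return tuple(entries)


@dataclass(frozen=True)
class PeakPick:
    position_cm1: float
    fwhm_cm1: float | None
    height: float


def find_nitrile_peak(
    wavenumbers: Sequence[float] | np.ndarray,
    intensities: Sequence[float] | np.ndarray,
    window: tuple[float, float] = NITRILE_WINDOW,
) -> PeakPick | None:
    """Locate the nitrile band in a spectrum.

    The window maximum is refined by a parabola through the three points
    around it; the width comes from linear interpolation of the
    half-height crossings above a median baseline.  Returns ``None``
    when the window maximum does not rise 5 robust-sigma above the
    baseline — a threshold high enough that the extreme order statistic
    of ~10^2 pure-noise samples does not read as a peak.
    """
    x = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("wavenumbers and intensities must be matching 1-d arrays")
    if x.size > 1 and np.any(np.diff(x) <= 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    lo, hi = window
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 10:
        raise ValueError(f"spectrum covers the window {window} with fewer than 10 points")
    xs, ys = x[mask], y[mask]

    baseline = float(np.median(ys))
    noise = 1.4826 * float(np.median(np.abs(ys - baseline)))  # robust sigma (MAD)
    i = int(np.argmax(ys))
    height = ys[i] - baseline
    if height < 5.0 * max(noise, 1e-30):
        return None

    # parabolic vertex through (i-1, i, i+1)
    if 0 < i < xs.size - 1:
        y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        pos = xs[i] + delta * (xs[min(i + 1, xs.size - 1)] - xs[max(i - 1, 0)]) / 2
    else:
        pos = xs[i]

    half = baseline + height / 2.0
    fwhm = None
    left = right = None
    for j in range(i, 0, -1):
        if ys[j - 1] <= half <= ys[j]:
            frac = (half - ys[j - 1]) / (ys[j] - ys[j - 1])
            left = xs[j - 1] + frac * (xs[j] - xs[j - 1])
            break
    for j in range(i, xs.size - 1):
        if ys[j + 1] <= half <= ys[j]:
            frac = (ys[j] - half) / (ys[j] - ys[j + 1])
            right = xs[j] + frac * (xs[j + 1] - xs[j])
            break
    if left is not None and right is not None:
        fwhm = float(right - left)
    return PeakPick(position_cm1=float(pos), fwhm_cm1=fwhm, height=float(height))


def assign_polymorph(
    obs: CrystalObservation,
    library: Iterable[RamanReferenceEntry] | None = None,
    shift_tol_cm1: float = DEFAULT_SHIFT_TOL,
) -> AssignmentResult:
    """Assign a polymorph label to one crystal observation.

    Candidates within ``shift_tol_cm1`` of the measured nu_CN are
    filtered by color, then habit (when the observation records them and
    at least one candidate survives the filter); the survivor with the
    smallest residual wins.  An exact residual tie among survivors is
    reported as ambiguous; an empty candidate set as unassigned.
    """
    entries = tuple(library) if library is not None else default_library()
    if not entries:
        raise ValueError("reference library is empty")

    cands = [e for e in entries if e.residual(obs.nu_cn_cm1) <= shift_tol_cm1]
    if not cands:
        return AssignmentResult(None, "unassigned", None)
    narrowed = len(cands) > 1

    for attr in ("color", "habit"):
        val = getattr(obs, attr)
        if val is None or len(cands) == 1:
            continue
        kept = [
            e for e in cands
            if getattr(e, attr) == "any" or getattr(e, attr).lower() == val.lower()
        ]
        if kept:  # never let an attribute filter empty the set outright
            cands = kept

    # deterministic ordering: residual, then id
    cands.sort(key=lambda e: (e.residual(obs.nu_cn_cm1), e.polymorph_id))
    best = cands[0]
    best_res = best.residual(obs.nu_cn_cm1)
    tied = [e for e in cands if e.residual(obs.nu_cn_cm1) == best_res]
    if len(tied) > 1:
        return AssignmentResult(
            None,
            "ambiguous",
            float(best_res),
            candidates=tuple(e.polymorph_id for e in cands),
        )
    if best.tentative:
        conf = "tentative"
    elif narrowed:
        conf = "disambiguated_by_attributes"
    else:
        conf = "unambiguous"
    return AssignmentResult(
        best.polymorph_id,
        conf,
        float(best_res),
        candidates=tuple(e.polymorph_id for e in cands),
    )


def summarize_composition(assignments: Sequence[AssignmentResult]) -> CompositionSummary:
    """Tally assigned polymorph counts; ambiguous/unassigned are kept separate."""
    if not assignments:
        raise ValueError("no assignments to summarize")
    counts: Counter[str] = Counter()
    n_amb = n_un = 0
    for a in assignments:
        if a.confidence == "ambiguous":
            n_amb += 1
        elif a.confidence == "unassigned":
            n_un += 1
        else:
            counts[a.polymorph_id] += 1
    n_assigned = sum(counts.values())
    fractions = {
        pid: c / n_assigned for pid, c in sorted(counts.items())
    } if n_assigned else {}
    return CompositionSummary(
        counts=dict(sorted(counts.items())),
        total_n=len(assignments),
        n_assigned=n_assigned,
        n_ambiguous=n_amb,
        n_unassigned=n_un,
        fractions=fractions,
    )
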