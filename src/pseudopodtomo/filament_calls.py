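"""Per-filament polarity calls and tip-ward / cell-ward fraction summaries.

Segment votes are aggregated per filament by majority, with an exact
binomial confidence criterion against the chance hypothesis p = 1/2:
``confidence_p = P(X >= max(n_plus, n_minus))`` for
``X ~ Binomial(n_plus + n_minus, 1/2)``. A filament is resolved when the
tail probability is at most alpha and enough nonzero votes were cast;
exact ties are unresolved. Resolved filaments are then classified as
tip-ward or cell-ward by the sign of their barbed-end direction against
the protrusion tip axis, and fractions are averaged across tomograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .scene import FilamentTrace
from .segments import SegmentRecord

ALPHA_DEFAULT = 0.05
ALPHA_STRINGENT = 0.01
N_MIN_DEFAULT = 5


@dataclass
class FilamentPolarityCall:
    filament_id: int
    n_votes: int
    n_plus: int
    n_minus: int
    majority_fraction: float      # in [0.5, 1] when votes exist
    confidence_p: float
    majority_sign: int            # +1 / -1 along +trace order, 0 unresolved
    call: str = "unresolved"      # {"tip-ward", "cell-ward", "unresolved"}

    @property
    def resolved(self) -> bool:
        return self.majority_sign != 0


@dataclass
class PolarityFractionSummary:
    per_tomogram: list[dict]      # tomogram_id, resolved_count, tip_ward_fraction, ...
    aggregate_mean: float         # percent tip-ward among resolved
    aggregate_sd: float           # percent, SD across tomograms
    criterion: str = "default"
    excluded_tomograms: list = field(default_factory=list)

    @property
    def cell_ward_mean(self) -> float:
        return 100.0 - self.aggregate_mean


def vote_filament(votes: list[int] | np.ndarray, alpha: float = ALPHA_DEFAULT,
                  n_min: int = N_MIN_DEFAULT,
                  filament_id: int = -1) -> FilamentPolarityCall:
    """Majority call over one filament's segment votes.

    ``votes`` are +1 / -1 / 0; zeros (abstentions from discarded classes)
    do not count toward the binomial test. Empty input is unresolved with
    ``n_votes = 0``.
    """
    votes = np.asarray(votes, dtype=int)
    n_votes = len(votes)
    n_plus = int(np.sum(votes == 1))
    n_minus = int(np.sum(votes == -1))
    n = n_plus + n_minus
    if n == 0:
        return FilamentPolarityCall(filament_id, n_votes, 0, 0, 0.5, 1.0, 0)
    n_maj = max(n_plus, n_minus)
    majority_fraction = n_maj / n
    confidence_p = float(stats.binom.sf(n_maj - 1, n, 0.5))
    sign = 0
    if n_plus != n_minus and confidence_p <= alpha and n >= n_min:
        sign = 1 if n_plus > n_minus else -1
    return FilamentPolarityCall(filament_id, n_votes, n_plus, n_minus,
                                majority_fraction, confidence_p, sign)


def calls_from_records(records: list[SegmentRecord], alpha: float = ALPHA_DEFAULT,
                       n_min: int = N_MIN_DEFAULT) -> dict[int, FilamentPolarityCall]:
    by_fil: dict[int, list[int]] = {}
    for rec in records:
        by_fil.setdefault(rec.filament_id, []).append(rec.polarity_vote)
    return {fid: vote_filament(v, alpha, n_min, fid)
            for fid, v in sorted(by_fil.items())}


def tip_direction(membrane_mask: np.ndarray | None,
                  pixel_size: float = 1.0,
                  override: np.ndarray | None = None) -> np.ndarray:
    """Unit tip axis of a protrusion from its membrane mask.

    The axis is the principal axis of the membrane voxel cloud, oriented
    toward the capped (free) end -- detected as the axial end whose
    terminal slab contains membrane voxels close to the axis (a cap
    closes the tube cross-section; an open end is an annulus). An
    ``override`` vector short-circuits the estimate (returned
    normalized).
    """
    if override is not None:
        v = np.asarray(override, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("override vector must be nonzero")
        return v / n
    if membrane_mask is None or not np.any(membrane_mask):
        raise ValueError("membrane mask empty and no override given")
    zz, yy, xx = np.nonzero(membrane_mask)
    pts = np.column_stack([xx, yy, zz]).astype(float) * pixel_size
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    w, v = np.linalg.eigh(cov)
    if w[-1] < 1.5 * w[-2]:
        raise ValueError(
            "membrane mask has no clear principal axis; supply an override")
    axis = v[:, -1]
    proj = centred @ axis
    perp = np.sqrt(np.maximum((centred ** 2).sum(axis=1) - proj ** 2, 0.0))
    extent = proj.max() - proj.min()
    r_typ = np.median(perp)

    def _closed(at_max: bool) -> bool:
        if at_max:
            sel = proj > proj.max() - 0.08 * extent
        else:
            sel = proj < proj.min() + 0.08 * extent
        return bool(np.any(sel)) and perp[sel].min() < 0.3 * r_typ

    hi, lo = _closed(True), _closed(False)
    if hi == lo:
        raise ValueError(
            "could not identify a unique capped end of the membrane mask; "
            "supply an override tip direction")
    if lo:
        axis = -axis
    return axis / np.linalg.norm(axis)


def barbed_end_direction(call: FilamentPolarityCall,
                         trace: FilamentTrace) -> np.ndarray | None:
    """Barbed-end unit vector implied by a resolved call, in the trace's
    chord frame (None when unresolved)."""
    if not call.resolved:
        return None
    return call.majority_sign * trace.chord_direction


def summarize_fractions(per_tomogram: list[dict],
                        criterion: str = "default") -> PolarityFractionSummary:
    """Cross-tomogram tip-ward / cell-ward fraction summary.

    ``per_tomogram`` entries carry ``tomogram_id``, ``calls`` (dict
    filament_id -> FilamentPolarityCall), ``traces`` (dict filament_id ->
    FilamentTrace) and ``tip_axis``. A resolved filament counts tip-ward
    when its barbed-end direction has positive dot product with the tip
    axis; an exactly zero dot product counts cell-ward (conservative).
    Fractions are over resolved filaments only; tomograms without any
    resolved filament are excluded and reported.
    """
    rows = []
    excluded = []
    for entry in per_tomogram:
        calls = entry["calls"]
        traces = entry["traces"]
        tip_axis = np.asarray(entry["tip_axis"], dtype=float)
        tip_axis = tip_axis / np.linalg.norm(tip_axis)
        n_tip = n_cell = 0
        for fid, call in calls.items():
            b = barbed_end_direction(call, traces[fid])
            if b is None:
                continue
            d = float(b @ tip_axis)
            if d > 0:
                call.call = "tip-ward"
                n_tip += 1
            else:
                call.call = "cell-ward"
                n_cell += 1
        resolved = n_tip + n_cell
        if resolved == 0:
            excluded.append(entry["tomogram_id"])
            continue
        rows.append({
            "tomogram_id": entry["tomogram_id"],
            "n_filaments": len(calls),
            "resolved_count": resolved,
            "unresolved_count": len(calls) - resolved,
            "tip_ward_count": n_tip,
            "cell_ward_count": n_cell,
            "tip_ward_fraction": n_tip / resolved,
            "tip_ward_fraction_of_total": n_tip / len(calls) if calls else 0.0,
        })
    if not rows:
        raise ValueError("no tomogram contributed a resolved filament")
    fracs = np.array([r["tip_ward_fraction"] for r in rows])
    mean = 100.0 * float(fracs.mean())
    sd = 100.0 * float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0
    return PolarityFractionSummary(rows, mean, sd, criterion, excluded)
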