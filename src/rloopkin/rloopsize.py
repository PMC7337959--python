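"""R-loop sizing from supercoiling rotation curves.

A trapped R-loop unwinds ~2 turns of DNA; with the magnet turns held
constant this shifts the negative flank of the extension-vs-turns "hat"
curve horizontally.  The shift is estimated pairwise between every
reference curve (no enzyme) and every R-loop-trapped curve by comparing
fitted flank lines at a matched extension, aggregated as mean +/- SD over
all pairs, and converted to base pairs by calibrating against conditions
assumed to form the full-length (20 bp) R-loop.  Conditions are compared
with a one-way ANOVA followed by all-pairs Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import FlankFitError, InvalidPairError

__all__ = [
    "RotationCurve",
    "FlankFit",
    "RLoopSizeEstimate",
    "fit_linear_flank",
    "estimate_turn_shift",
    "aggregate_shifts",
    "turns_to_bp",
    "compare_groups",
]

#: flank points must lie below this fraction of the plateau extension
_PLATEAU_FRACTION = 0.90
#: and at least this many turns beyond the curve apex
_APEX_MARGIN = 2.0
_MIN_FLANK_POINTS = 5
#: pairwise comparison is invalid beyond this relative slope mismatch
_SLOPE_MISMATCH = 0.20


@dataclass
class RotationCurve:
    """Mean bead extension vs applied magnet turns (sizing curves are
    recorded at 1 turn/s)."""

    curve_id: str
    magnet_turns: np.ndarray
    extension: np.ndarray
    condition: str = "reference"  # reference | rloop_trapped
    rotation_rate: float = 1.0

    def __post_init__(self) -> None:
        self.magnet_turns = np.asarray(self.magnet_turns, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.magnet_turns.size != self.extension.size:
            raise ValueError("turns and extension must have equal length")
        if self.magnet_turns.size < 10:
            raise ValueError("rotation curve needs >= 10 points")
        d = np.diff(self.magnet_turns)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("magnet_turns must be monotonic along acquisition")


@dataclass
class FlankFit:
    """OLS line fitted to one flank of a hat curve."""

    slope: float  # um per turn
    intercept: float  # um at 0 turns
    r_squared: float
    side: str
    n_points: int
    extension_range: tuple = (0.0, 0.0)

    def turns_at(self, extension: float) -> float:
        return (extension - self.intercept) / self.slope


@dataclass
class RLoopSizeEstimate:
    """Aggregate of all pairwise turn shifts for one condition."""

    pairwise_shifts: np.ndarray
    mean_turns: float
    sd_turns: float
    n_pairs: int
    n_invalid: int
    bp: float | None = None
    calibration_set: list = field(default_factory=list)

    def cumulative_probability(self) -> pd.DataFrame:
        """Plot-ready cumulative distribution of the pairwise shifts."""
        shifts = np.sort(self.pairwise_shifts)
        return pd.DataFrame(
            {
                "shift_turns": shifts,
                "cumulative_probability": np.arange(1, shifts.size + 1) / shifts.size,
            }
        )


def _apex(curve: RotationCurve) -> tuple:
    """Plateau extension and apex turn position (centroid of the top of
    the hat, robust to noise)."""
    ext = curve.extension
    plateau = float(np.quantile(ext, 0.98))
    top = ext >= plateau - 0.02 * abs(plateau)
    apex_turns = float(np.mean(curve.magnet_turns[top]))
    return plateau, apex_turns


def fit_linear_flank(curve: RotationCurve, side: str = "negative") -> FlankFit:
    """OLS line on the linear flank past the buckling shoulder.

    The flank is the set of points with extension below 90% of the plateau
    and at least 2 turns beyond the apex on the requested side.  Raises
    FlankFitError if fewer than 5 such points exist or the region is not a
    valid descending flank (|slope| indistinguishable from zero).
    """
    if side not in ("negative", "positive"):
        raise ValueError("side must be 'negative' or 'positive'")
    plateau, apex_turns = _apex(curve)
    below = curve.extension < _PLATEAU_FRACTION * plateau
    if side == "negative":
        mask = below & (curve.magnet_turns < apex_turns - _APEX_MARGIN)
    else:
        mask = below & (curve.magnet_turns > apex_turns + _APEX_MARGIN)
    if np.count_nonzero(mask) < _MIN_FLANK_POINTS:
        raise FlankFitError(
            f"only {np.count_nonzero(mask)} points past the buckling shoulder "
            f"on the {side} flank (need >= {_MIN_FLANK_POINTS})"
        )
    x = curve.magnet_turns[mask]
    y = curve.extension[mask]
    reg = stats.linregress(x, y)
    slope, intercept = float(reg.slope), float(reg.intercept)
    se = float(reg.stderr) if np.isfinite(reg.stderr) else 0.0
    if abs(slope) <= 3 * se or slope == 0.0:
        raise FlankFitError("selected region is flat: slope not resolvable from noise")
    expected_sign = 1.0 if side == "negative" else -1.0
    if np.sign(slope) != expected_sign:
        raise FlankFitError(
            f"{side} flank slope has the wrong sign ({slope:+.3g} um/turn)"
        )
    return FlankFit(
        slope=slope,
        intercept=intercept,
        r_squared=float(reg.rvalue**2),
        side=side,
        n_points=int(np.count_nonzero(mask)),
        extension_range=(float(y.min()), float(y.max())),
    )


def estimate_turn_shift(
    reference: RotationCurve,
    rloop: RotationCurve,
    side: str = "negative",
) -> float:
    """Horizontal offset in turns between the flank lines of a reference
    and an R-loop-trapped curve, resolved at the midpoint extension of the
    overlapping flank range (positive shift = turns absorbed by the
    R-loop).  Raises InvalidPairError if the slopes differ by > 20%."""
    ref_fit = fit_linear_flank(reference, side)
    rl_fit = fit_linear_flank(rloop, side)
    mismatch = abs(ref_fit.slope - rl_fit.slope) / abs(ref_fit.slope)
    if mismatch > _SLOPE_MISMATCH:
        raise InvalidPairError(
            f"flank slopes differ by {mismatch:.0%} (> {_SLOPE_MISMATCH:.0%}): "
            f"{reference.curve_id} vs {rloop.curve_id}"
        )
    lo = max(ref_fit.extension_range[0], rl_fit.extension_range[0])
    hi = min(ref_fit.extension_range[1], rl_fit.extension_range[1])
    y_mid = 0.5 * (lo + hi)
    shift = ref_fit.turns_at(y_mid) - rl_fit.turns_at(y_mid)
    if side == "positive":
        shift = -shift
    return float(shift)


def aggregate_shifts(
    references: list,
    rloops: list,
    side: str = "negative",
) -> RLoopSizeEstimate:
    """All-pairs turn-shift estimates between reference and R-loop curve
    sets (the study design pairs 20 references with 22 trapped curves,
    i.e. 440 estimates); invalid pairs are dropped, with a hard error if
    more than half are invalid."""
    if len(references) < 2 or len(rloops) < 2:
        raise ValueError("need >= 2 curves per set")
    shifts = []
    n_invalid = 0
    for ref in references:
        for rl in rloops:
            try:
                shifts.append(estimate_turn_shift(ref, rl, side))
            except (InvalidPairError, FlankFitError):
                n_invalid += 1
    n_total = len(references) * len(rloops)
    if n_invalid > 0.5 * n_total:
        raise InvalidPairError(
            f"{n_invalid}/{n_total} curve pairs invalid: sets are not comparable"
        )
    shifts = np.asarray(shifts, dtype=float)
    return RLoopSizeEstimate(
        pairwise_shifts=shifts,
        mean_turns=float(np.mean(shifts)),
        sd_turns=float(np.std(shifts, ddof=1)),
        n_pairs=int(shifts.size),
        n_invalid=n_invalid,
    )


def turns_to_bp(
    estimate: RLoopSizeEstimate,
    fulllength_estimates,
    fulllength_bp: float = 20.0,
    calibration_set: list | None = None,
) -> RLoopSizeEstimate:
    """Convert the mean trapped-turn shift to base pairs, calibrating the
    turns-per-bp scale on conditions assumed to form the full-length
    (default 20 bp) R-loop:  bp = fulllength_bp * mean_turns / mean(cal)."""
    cal = np.asarray(list(fulllength_estimates), dtype=float)
    if cal.size == 0 or np.any(cal <= 0):
        raise ValueError("full-length calibration estimates must be non-empty and > 0")
    cal_mean = float(np.mean(cal))
    estimate.bp = float(fulllength_bp * estimate.mean_turns / cal_mean)
    estimate.calibration_set = list(calibration_set or [])
    return estimate


def compare_groups(estimates_by_condition: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA over conditions followed by all-pairs Tukey HSD.

    A pair is called significant only when the ANOVA rejects at ``alpha``
    and its Tukey-adjusted p-value is below ``alpha`` (the protected
    sequence).  Zero-variance groups are flagged, not silently compared.
    Returns {"anova_f", "anova_p", "table": DataFrame, "degenerate": [...]}.
    """
    conditions = list(estimates_by_condition)
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    groups = []
    degenerate = []
    for c in conditions:
        g = np.asarray(estimates_by_condition[c], dtype=float)
        if g.size < 3:
            raise ValueError(f"condition {c!r} has < 3 estimates")
        if np.ptp(g) == 0:
            degenerate.append(c)
        groups.append(g)
    f_stat, anova_p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate([[c] * len(g) for c, g in zip(conditions, groups)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        tukey.summary().data[1:],
        columns=[str(c) for c in tukey.summary().data[0]],
    )
    table["p-adj"] = np.asarray(tukey.pvalues, dtype=float)
    table["meandiff"] = np.asarray(tukey.meandiffs, dtype=float)
    table["significant"] = (anova_p < alpha) & (table["p-adj"].to_numpy() < alpha)
    return {
        "anova_f": float(f_stat),
        "anova_p": float(anova_p),
        "table": table,
        "degenerate": degenerate,
        "alpha": alpha,
    }
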