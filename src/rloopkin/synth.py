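"""Synthetic instrument data with the statistical structure the analysis
assumes, plus machine-readable ground truth for every generated record.

Emulated signals:

* magnetic-tweezers bead traces at 60 Hz: piecewise-constant extension with
  an upward step (trapped turns x extension-per-turn) at exponentially
  distributed dwell times after each magnet transit, white Gaussian
  tracking noise;
* supercoiling rotation ("hat") curves: plateau with linear flanks past the
  buckling shoulder, negative flank shifted left by the trapped turns when
  an R-loop is held;
* plasmid-cleavage scintillation tables: Poisson counts around the
  sequential-model fractions;
* two-fluorophore emission spectra: Gaussian donor/acceptor bands with
  FRET-dependent sensitized acceptor emission.

All generators are deterministic given the config seed (per-generator
random streams are derived from it), so identical configs produce
byte-identical CSV output.  Curves and traces are phenomenological; no
polymer mechanics is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret import EmissionSpectrum
from .kinetics import CleavageTimeCourse, simulate_three_step, simulate_two_step
from .rloopsize import RotationCurve
from .traces import BeadTrace, Phase, RotationProtocol

__all__ = [
    "DwellLaw",
    "TraceConfig",
    "CleavageConfig",
    "CurveConfig",
    "SpectraConfig",
    "SynthConfig",
    "gen_bead_trace",
    "gen_rotation_curve",
    "gen_rotation_curves",
    "gen_time_course",
    "gen_spectra",
]


@dataclass
class DwellLaw:
    """Single-exponential or two-component-mixture dwell-time law."""

    tau: float | None = None
    slow_fraction: float | None = None
    tau_slow: float | None = None
    tau_fast: float | None = None

    def __post_init__(self) -> None:
        if self.tau is not None:
            if self.tau <= 0:
                raise ValueError("tau must be > 0")
        else:
            if None in (self.slow_fraction, self.tau_slow, self.tau_fast):
                raise ValueError("mixture law needs slow_fraction, tau_slow, tau_fast")
            if not 0 <= self.slow_fraction <= 1:
                raise ValueError("slow_fraction must lie in [0, 1]")
            if self.tau_slow <= 0 or self.tau_fast <= 0:
                raise ValueError("time constants must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.tau is not None:
            return rng.exponential(self.tau, size=n)
        slow = rng.random(n) < self.slow_fraction
        out = rng.exponential(self.tau_fast, size=n)
        out[slow] = rng.exponential(self.tau_slow, size=np.count_nonzero(slow))
        return out

    @property
    def mean(self) -> float:
        if self.tau is not None:
            return self.tau
        return self.slow_fraction * self.tau_slow + (1 - self.slow_fraction) * self.tau_fast


@dataclass
class TraceConfig:
    """Bead-trace generator settings (60 Hz camera, 10 turns/s cycling)."""

    sample_rate: float = 60.0
    noise_sd_um: float = 0.010
    nm_per_turn: float = 50.0
    full_rloop_turns: float = 1.9
    rloop_turns: float = 1.9  # turns actually trapped in this condition
    neg_target_turns: float = -15.0
    pos_target_turns: float = 15.0
    rotation_rate: float = 10.0
    neg_hold_s: float = 30.0
    pos_hold_s: float = 20.0
    baseline_um: float = 0.55
    n_cycles: int = 1
    formation: DwellLaw = field(default_factory=lambda: DwellLaw(tau=4.0))
    dissociation: DwellLaw = field(default_factory=lambda: DwellLaw(tau=2.0))

    @property
    def um_per_turn(self) -> float:
        return self.nm_per_turn / 1000.0

    @property
    def step_um(self) -> float:
        return self.rloop_turns * self.um_per_turn

    @property
    def full_step_um(self) -> float:
        return self.full_rloop_turns * self.um_per_turn


@dataclass
class CleavageConfig:
    """Scintillation-table generator settings (counts per gel lane)."""

    variant: str = "two_step"
    rates: dict = field(default_factory=lambda: {"k_a": 0.1, "k_b": 0.01})
    counts_per_lane: int = 2000
    times: tuple = (5.0, 10.0, 20.0, 40.0, 60.0, 120.0, 180.0, 300.0, 450.0, 600.0, 900.0, 1200.0)


@dataclass
class CurveConfig:
    """Rotation hat-curve generator settings (sizing curves at 1 turn/s)."""

    plateau_um: float = 0.90
    slope_um_per_turn: float = 0.05
    apex_turns: float = 0.0
    buckling_turns: float = 4.0
    noise_sd_um: float = 0.005
    turn_min: float = -20.0
    turn_max: float = 20.0
    turn_step: float = 0.5
    rotation_rate: float = 1.0


@dataclass
class SpectraConfig:
    """Two-fluorophore emission-spectra generator settings."""

    donor_center_nm: float = 565.0
    donor_sigma_nm: float = 18.0
    acceptor_center_nm: float = 667.0
    acceptor_sigma_nm: float = 14.0
    donor_amp: float = 1000.0
    acceptor_amp: float = 800.0
    fret_efficiency: float = 0.5
    sensitized_scale: float = 0.8  # acceptor photons per donor excitation transferred
    direct_530_fraction: float = 0.05  # direct acceptor excitation at 530 nm
    noise_sd: float = 0.5


@dataclass
class SynthConfig:
    """Seeded bundle of all generator settings; identical configs produce
    identical output."""

    seed: int = 0
    trace: TraceConfig = field(default_factory=TraceConfig)
    cleavage: CleavageConfig = field(default_factory=CleavageConfig)
    curve: CurveConfig = field(default_factory=CurveConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)

    def rng(self, *stream) -> np.random.Generator:
        """Independent random stream derived from the config seed."""
        return np.random.default_rng([int(self.seed), *(int(s) for s in stream)])


_STREAM_TRACE, _STREAM_CURVE, _STREAM_CLEAVAGE, _STREAM_SPECTRA = 1, 2, 3, 4


def gen_bead_trace(
    config: SynthConfig,
    index: int = 0,
    true_dwells: dict | None = None,
    trace_id: str | None = None,
):
    """Generate one bead trace plus its rotation protocol and ground truth.

    Each cycle is a negative hold (R-loop formation window) followed by a
    positive hold (dissociation window); every event is an upward extension
    step of rloop_turns x um_per_turn at a dwell drawn from the configured
    law (or taken from ``true_dwells`` = {"formation": [...],
    "dissociation": [...]}).  Dwells exceeding the hold duration are
    recorded as censored in the truth table, and the R-loop state carries
    over into subsequent phases.

    Returns (BeadTrace, RotationProtocol, truth DataFrame).
    """
    tc = config.trace
    rng = config.rng(_STREAM_TRACE, index)
    fs = tc.sample_rate
    step = tc.step_um
    b0 = tc.baseline_um

    phases = []
    segments = []  # (t_start, t_end, kind, params) building blocks
    truth_rows = []
    t_cursor = 0.0
    prev_target = 0.0
    level = b0  # extension level entering the first transit
    rloop = False
    provided = {"formation": list(true_dwells.get("formation", []))
                if true_dwells else [],
                "dissociation": list(true_dwells.get("dissociation", []))
                if true_dwells else []}

    for cycle in range(tc.n_cycles):
        for sense in ("negative", "positive"):
            target = tc.neg_target_turns if sense == "negative" else tc.pos_target_turns
            hold = tc.neg_hold_s if sense == "negative" else tc.pos_hold_s
            transit = abs(target - prev_target) / tc.rotation_rate
            start, end = t_cursor, t_cursor + transit + hold
            phases.append(Phase(start, end, target, tc.rotation_rate, sense))
            kind = "formation" if sense == "negative" else "dissociation"
            eventful = (kind == "formation" and not rloop) or (
                kind == "dissociation" and rloop
            )
            dwell = np.nan
            censored = False
            if eventful:
                if provided[kind]:
                    dwell = float(provided[kind].pop(0))
                else:
                    law = tc.formation if kind == "formation" else tc.dissociation
                    dwell = float(law.sample(rng, 1)[0])
                censored = dwell >= hold
                pre, post = b0, b0 + step
                hold_start_level = pre
            else:
                hold_start_level = b0 + step
                pre = post = hold_start_level
            segments.append((start, start + transit, "ramp", level, hold_start_level,
                             prev_target, target))
            segments.append((start + transit, end, "hold", pre, post,
                             (dwell if eventful and not censored else np.inf), target))
            level = post if (eventful and not censored) else hold_start_level
            truth_rows.append(
                {
                    "cycle": cycle,
                    "phase_index": len(phases) - 1,
                    "kind": kind,
                    "eventful": eventful,
                    "true_dwell_s": dwell,
                    "censored": censored,
                    "step_um": step if eventful else 0.0,
                }
            )
            if eventful and not censored:
                rloop = kind == "formation"
            t_cursor = end
            prev_target = target

    n_samples = int(round(t_cursor * fs))
    time = np.arange(n_samples) / fs
    extension = np.empty(n_samples)
    turns = np.empty(n_samples)
    for seg in segments:
        if seg[2] == "ramp":
            t0, t1, _, lv0, lv1, tr0, tr1 = seg
            m = (time >= t0 - 1e-12) & (time < t1 - 1e-12)
            if t1 > t0:
                frac = (time[m] - t0) / (t1 - t0)
            else:
                frac = np.zeros(np.count_nonzero(m))
            extension[m] = lv0 + frac * (lv1 - lv0)
            turns[m] = tr0 + frac * (tr1 - tr0)
        else:
            t0, t1, _, pre, post, dwell, target = seg
            m = (time >= t0 - 1e-12) & (time < t1 - 1e-12)
            rel = time[m] - t0
            extension[m] = np.where(rel < dwell, pre, post)
            turns[m] = target
    extension = extension + rng.normal(0.0, tc.noise_sd_um, size=n_samples)
    extension = np.maximum(extension, 1e-6)

    trace = BeadTrace(
        trace_id=trace_id or f"trace{index:03d}",
        time=time,
        extension=extension,
        magnet_turns=turns,
        sample_rate=fs,
    )
    protocol = RotationProtocol(phases=phases, initial_turns=0.0)
    return trace, protocol, pd.DataFrame(truth_rows)


def gen_rotation_curve(
    config: SynthConfig,
    trapped_turns: float = 0.0,
    index: int = 0,
    curve_id: str | None = None,
) -> RotationCurve:
    """Symmetric hat curve whose negative flank is shifted left by
    ``trapped_turns`` (the turns absorbed by a trapped R-loop), with
    Gaussian noise on extension."""
    cc = config.curve
    rng = config.rng(_STREAM_CURVE, index, int(round(trapped_turns * 1000)))
    turns = np.arange(cc.turn_min, cc.turn_max + cc.turn_step / 2, cc.turn_step)
    left_edge = cc.apex_turns - cc.buckling_turns - trapped_turns
    right_edge = cc.apex_turns + cc.buckling_turns
    ext = np.full_like(turns, cc.plateau_um, dtype=float)
    left = turns < left_edge
    right = turns > right_edge
    ext[left] -= cc.slope_um_per_turn * (left_edge - turns[left])
    ext[right] -= cc.slope_um_per_turn * (turns[right] - right_edge)
    if cc.noise_sd_um > 0:
        ext = ext + rng.normal(0.0, cc.noise_sd_um, size=ext.size)
    return RotationCurve(
        curve_id=curve_id or f"curve{index:03d}",
        magnet_turns=turns,
        extension=ext,
        condition="rloop_trapped" if trapped_turns != 0 else "reference",
        rotation_rate=cc.rotation_rate,
    )


def gen_rotation_curves(
    config: SynthConfig,
    n: int,
    trapped_turns: float = 0.0,
    prefix: str = "curve",
    index_offset: int = 0,
) -> list:
    """A set of independently noised curves sharing one trapped-turn truth
    (the study design uses 20 reference and 22 trapped curves)."""
    return [
        gen_rotation_curve(
            config,
            trapped_turns,
            index=index_offset + i,
            curve_id=f"{prefix}{index_offset + i:03d}",
        )
        for i in range(n)
    ]


def gen_time_course(
    config: SynthConfig,
    replicate_id: str = "rep0",
    index: int = 0,
) -> CleavageTimeCourse:
    """Scintillation-count time course: per lane and species, counts are
    Poisson with mean = model fraction x counts_per_lane."""
    cl = config.cleavage
    rng = config.rng(_STREAM_CLEAVAGE, index)
    times = np.asarray(cl.times, dtype=float)
    if cl.variant == "two_step":
        model = simulate_two_step(cl.rates["k_a"], cl.rates["k_b"], times)
    else:
        model = simulate_three_step(
            cl.rates["k_formation"], cl.rates["k_a"], cl.rates["k_b"], times
        )
    frac = model.stacked()
    counts = rng.poisson(frac * cl.counts_per_lane)
    return CleavageTimeCourse(
        replicate_id=replicate_id,
        times=times,
        sc=counts[0].astype(float),
        oc=counts[1].astype(float),
        lin=counts[2].astype(float),
        is_fraction=False,
    )


def gen_spectra(config: SynthConfig, index: int = 0):
    """Emission spectra under 530 and 630 nm excitation.

    The 530 nm spectrum holds a donor band scaled by (1 - E), a sensitized
    acceptor band scaled by E x sensitized_scale x donor_amp, and a small
    directly excited acceptor band; the 630 nm spectrum holds the acceptor
    band only.  Returns (spec530, spec630, truth dict with the component
    amplitudes).
    """
    sp = config.spectra
    rng = config.rng(_STREAM_SPECTRA, index)
    e = sp.fret_efficiency
    if not 0 <= e <= 1:
        raise ValueError("fret_efficiency must lie in [0, 1]")

    def band(grid, center, sigma, amp):
        return amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)

    grid530 = np.arange(550.0, 800.0 + 0.5, 1.0)
    grid630 = np.arange(650.0, 800.0 + 0.5, 1.0)
    sensitized_amp = e * sp.sensitized_scale * sp.donor_amp
    direct530_amp = sp.direct_530_fraction * sp.acceptor_amp
    i530 = (
        band(grid530, sp.donor_center_nm, sp.donor_sigma_nm, sp.donor_amp * (1 - e))
        + band(grid530, sp.acceptor_center_nm, sp.acceptor_sigma_nm,
               sensitized_amp + direct530_amp)
    )
    i630 = band(grid630, sp.acceptor_center_nm, sp.acceptor_sigma_nm, sp.acceptor_amp)
    if sp.noise_sd > 0:
        i530 = i530 + rng.normal(0.0, sp.noise_sd, size=i530.size)
        i630 = i630 + rng.normal(0.0, sp.noise_sd, size=i630.size)
    i530 = np.maximum(i530, 0.0)
    i630 = np.maximum(i630, 0.0)
    truth = {
        "fret_efficiency": e,
        "donor_amp": sp.donor_amp * (1 - e),
        "sensitized_amp": sensitized_amp,
        "direct_530_amp": direct530_amp,
        "direct_630_amp": sp.acceptor_amp,
    }
    return (
        EmissionSpectrum(530.0, grid530, i530),
        EmissionSpectrum(630.0, grid630, i630),
        truth,
    )
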