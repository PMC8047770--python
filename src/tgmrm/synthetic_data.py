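"""Synthetic MRM peak tables with known ground truth, and the
subset-removal prediction-recovery benchmark.

The generator emulates the export of an upstream peak-picking tool run on a
targeted TG acquisition: every true TG contributes, per chromatographic
variant, one co-eluting neutral-loss peak per distinct chain, sharing a
retention window whose borders are jittered slightly per channel (real
deconvolution never yields perfectly identical borders).  Intensities follow
a per-TG base level spread across chains by per-channel response
multipliers; channels can be dropped at random to emulate losses the
prediction function should recover.  All randomness is driven by a single
integer seed.

The benchmark removes a fixed fraction of peak rows at random, re-runs
identification on the subset, and measures what percentage of the TG species
lost relative to the full run the prediction function recovers — repeated
over independently seeded subsets, optionally protecting abundant chains
(e.g. 16:0, 18:0, 18:1) from removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .identifier import (
    PeakRecord,
    TGAssignment,
    Thresholds,
    identify_structures,
    predict_structures,
)
from .lipid_model import (
    FattyAcyl,
    TGComposition,
    brutto_ammonium_adduct_mz,
)

__all__ = [
    "SimulationConfig",
    "simulate_peak_table",
    "prediction_recovery_benchmark",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated acquisition.

    rt_window        usable gradient span in minutes
    peak_width_mean  mean chromatographic peak width (min)
    peak_width_jitter  half-range of uniform width jitter (min)
    border_jitter_frac per-channel border jitter as a fraction of width;
                       kept small so co-eluting channels overlap well above
                       the default 75% gate
    base_intensity_range  per-TG base intensity drawn log-uniformly (AUC-like)
    chain_multiplier_range per-channel response multiplier, uniform
    drop_probability chance each chain's loss peak is omitted
    isomer_count     chromatographic variants per composition (regioisomers)
    """

    true_tg_set: tuple[TGComposition, ...]
    rt_window: tuple[float, float] = (1.0, 25.0)
    peak_width_mean: float = 0.30
    peak_width_jitter: float = 0.05
    border_jitter_frac: float = 0.04
    base_intensity_range: tuple[float, float] = (1e4, 1e6)
    chain_multiplier_range: tuple[float, float] = (0.2, 1.0)
    drop_probability: float = 0.0
    isomer_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_tg_set:
            raise ValueError("true_tg_set is empty: nothing to simulate")
        if not (0.0 <= self.drop_probability <= 1.0):
            raise ValueError("drop_probability must be within [0, 1]")
        if not (self.rt_window[0] < self.rt_window[1]):
            raise ValueError("rt_window bounds must be ordered")
        if self.isomer_count < 1:
            raise ValueError("isomer_count must be >= 1")
        if self.peak_width_mean <= 2 * self.peak_width_jitter:
            raise ValueError("peak_width_mean too small for the jitter range")


@dataclass(frozen=True)
class GroundTruth:
    """One simulated TG variant and the chains whose peaks survived."""

    composition: TGComposition
    variant: int
    rt_center: float
    dropped_chains: tuple[FattyAcyl, ...]

    @property
    def complete(self) -> bool:
        return not self.dropped_chains

    @property
    def chain_multiset(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(fa.key for fa in self.composition.chains))


def simulate_peak_table(
    config: SimulationConfig,
) -> tuple[list[PeakRecord], list[GroundTruth]]:
    """Generate a peak table and its ground truth; deterministic per seed.

    Peak letters are assigned a, b, c, ... per (q1, q3_fa) channel in
    retention-time order, as an upstream deconvolution tool would.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.rt_window
    margin = config.peak_width_mean + config.peak_width_jitter

    comps = sorted(
        config.true_tg_set, key=lambda c: tuple(fa.key for fa in c.chains)
    )
    raw: list[tuple[TGComposition, int, float, FattyAcyl, float, float, float]] = []
    truths: list[GroundTruth] = []
    for comp in comps:
        for variant in range(config.isomer_count):
            center = rng.uniform(lo + margin, hi - margin)
            width = config.peak_width_mean + rng.uniform(
                -config.peak_width_jitter, config.peak_width_jitter
            )
            base = math.exp(
                rng.uniform(*np.log(config.base_intensity_range))
            )
            dropped: list[FattyAcyl] = []
            for fa in comp.distinct_chains:
                jit = config.border_jitter_frac * width
                left = center - width / 2 + rng.uniform(-jit, jit)
                right = center + width / 2 + rng.uniform(-jit, jit)
                mult = rng.uniform(*config.chain_multiplier_range)
                keep = rng.random() >= config.drop_probability
                if keep:
                    raw.append(
                        (comp, variant, center, fa, left, right, base * mult)
                    )
                else:
                    dropped.append(fa)
            truths.append(
                GroundTruth(
                    composition=comp,
                    variant=variant,
                    rt_center=center,
                    dropped_chains=tuple(dropped),
                )
            )

    # assign letters per (q1, q3_fa) channel in RT order
    peaks: list[PeakRecord] = []
    channels: dict[tuple[str, tuple[int, int]], list[tuple]] = {}
    for rec in raw:
        comp, variant, center, fa, left, right, intensity = rec
        q1 = f"{brutto_ammonium_adduct_mz(comp.brutto):.1f}"
        channels.setdefault((q1, fa.key), []).append(rec)
    for (q1, fa_key), recs in sorted(channels.items()):
        recs.sort(key=lambda r: r[4])  # by left border
        if len(recs) > 26:
            raise ValueError(
                f"channel (q1={q1}, q3={fa_key[0]}:{fa_key[1]}) has more than "
                "26 peaks; letters a-z exhausted"
            )
        for i, (comp, variant, center, fa, left, right, intensity) in enumerate(recs):
            peaks.append(
                PeakRecord(
                    name=f"{comp.brutto.label}_{fa}",
                    brutto=comp.brutto,
                    q1=q1,
                    q3_fa=fa,
                    peak_letter=chr(ord("a") + i),
                    rt_left=round(left, 4),
                    rt_right=round(right, 4),
                    intensity=round(intensity, 2),
                )
            )
    peaks.sort(key=lambda p: (p.q1, p.q3_fa.key, p.peak_letter))
    return peaks, truths


# ---------------------------------------------------------------------------
# Prediction-recovery benchmark
# ---------------------------------------------------------------------------

def _species(assignments: Sequence[TGAssignment]) -> set[tuple[tuple[int, int], ...]]:
    """TG species as bare chain multisets (letters and suffixes ignored)."""
    return {a.chain_multiset for a in assignments}


def prediction_recovery_benchmark(
    peaks: Sequence[PeakRecord],
    fa_list: Sequence[FattyAcyl],
    thresholds: Thresholds = Thresholds(),
    removal_fraction: float = 0.05,
    n_repeats: int = 10,
    protect_fas: Sequence[FattyAcyl] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Subset-removal test of the prediction function.

    Per repeat: remove ``floor(removal_fraction * N)`` random peak rows
    (never rows whose loss chain is protected), run identification on the
    subset, and compute

        recovery % = 100 * |missing species recovered by prediction|
                         / |species identified from the full table but
                            not from the subset|

    with species compared as chain multisets.  A repeat with no missing
    species is reported with NaN recovery (undefined, skipped).  Returns a
    per-repeat DataFrame with columns repeat, n_removed, n_missing,
    n_recovered, recovery_pct.
    """
    if not (0.0 < removal_fraction < 1.0):
        raise ValueError(
            f"removal_fraction must be in (0, 1), got {removal_fraction}"
        )
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    peaks = list(peaks)
    protected = {fa.key for fa in protect_fas}
    removable = [i for i, p in enumerate(peaks) if p.q3_fa.key not in protected]
    n_remove = min(int(removal_fraction * len(peaks)), len(removable))

    full_identified = _species(identify_structures(peaks, fa_list, thresholds))

    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    for rep, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        if n_remove == 0:
            rows.append((rep, 0, 0, 0, float("nan")))
            continue
        removed = set(rng.choice(removable, size=n_remove, replace=False).tolist())
        subset = [p for i, p in enumerate(peaks) if i not in removed]
        sub_identified = _species(identify_structures(subset, fa_list, thresholds))
        missing = full_identified - sub_identified
        if not missing:
            rows.append((rep, n_remove, 0, 0, float("nan")))
            continue
        sub_predicted = _species(predict_structures(subset, fa_list, thresholds))
        recovered = missing & sub_predicted
        rows.append(
            (
                rep,
                n_remove,
                len(missing),
                len(recovered),
                100.0 * len(recovered) / len(missing),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["repeat", "n_removed", "n_missing", "n_recovered", "recovery_pct"],
    )
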