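"""Synthetic experimental datasets for the labelling pipeline.

Two generators emulate the statistical structure of the wet-lab
measurements the chemistry calculators consume, so every analysis stage
is testable without laboratory data:

* :func:`gen_incorporation` — ITLC incorporation yield vs peptide amount:
  a logistic dose–response (midpoint 2.4 nmol, slope 0.25 nmol, asymptote
  99 %) plus Gaussian noise on the percent scale, clamped to [0, 100].
* :func:`gen_stability` — RCP vs time at several ascorbic-acid
  concentrations: exponential decay RCP(t) = RCP₀(c)·e^{−k(c)t} with a
  decay rate that falls to ~0 above 0.9 mmol/L quencher, plus noise.

Both return tidy DataFrames carrying their truth parameters in
``DataFrame.attrs["truth"]`` so recovery tests can compare against the
generating values.  The exponential RCP decay is a modelling choice (the
underlying radiolysis kinetics are not parameterized here); clamping to
[0, 100] slightly biases values near the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labelling import logistic

__all__ = ["GeneratorConfig", "gen_incorporation", "gen_stability"]

#: measured RCP (%) directly after labelling at each quencher level —
#: baseline map for the stability generator
DEFAULT_RCP0 = {
    0.0: 4.0,
    0.1: 75.0,
    0.3: 83.0,
    0.9: 87.0,
    2.6: 86.0,
    7.9: 86.0,
    24.0: 87.0,
    71.0: 88.0,
}


@dataclass
class GeneratorConfig:
    """Design and truth parameters for both generators.

    Defaults mirror the study design: ≥ 3 replicates per condition,
    peptide amounts bracketing the 2.4 nmol midpoint (the measured design
    points 1.7/3.5/7.0 nmol plus transition points), Gaussian noise of
    3 % SD on the percent scale, stability sampled over 0–120 min at
    quencher levels from 0 to 71 mmol/L.
    """

    seed: int = 0
    n_replicates: int = 3
    noise_sd_pct: float = 3.0
    peptide_amounts_nmol: tuple = (1.7, 2.0, 2.2, 2.4, 2.6, 2.8, 3.2, 3.5, 7.0)
    m50_nmol: float = 2.4
    slope_nmol: float = 0.25
    asymptote_pct: float = 99.0
    time_points_min: tuple = (0.0, 30.0, 60.0, 90.0, 120.0)
    ascorbic_mmol_L: tuple = (0.0, 0.1, 0.3, 0.9, 2.6, 7.9, 24.0, 71.0)
    rcp0_pct: dict = field(default_factory=lambda: dict(DEFAULT_RCP0))
    #: decay rate (1/min) with no quencher; falls linearly to 0 at 0.9 mmol/L
    k0_per_min: float = 0.006
    k_threshold_mmol_L: float = 0.9

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")
        if any(a <= 0 for a in self.peptide_amounts_nmol):
            raise ValueError("peptide amounts must be positive")

    def decay_rate_per_min(self, ascorbic_mmol_L: float) -> float:
        """k(c): linearly decreasing in quencher, ~0 at and above the
        0.9 mmol/L protection threshold."""
        return self.k0_per_min * max(0.0, 1.0 - ascorbic_mmol_L / self.k_threshold_mmol_L)

    def truth(self) -> dict:
        return {
            "m50_nmol": self.m50_nmol,
            "slope_nmol": self.slope_nmol,
            "asymptote_pct": self.asymptote_pct,
            "noise_sd_pct": self.noise_sd_pct,
            "k0_per_min": self.k0_per_min,
            "k_threshold_mmol_L": self.k_threshold_mmol_L,
            "rcp0_pct": dict(self.rcp0_pct),
        }


def gen_incorporation(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Synthetic ITLC incorporation measurements.

    Returns a DataFrame with columns ``peptide_nmol, replicate,
    incorporation_pct``; truth parameters in ``.attrs["truth"]``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for m in cfg.peptide_amounts_nmol:
        mean = logistic(m, cfg.m50_nmol, cfg.slope_nmol, cfg.asymptote_pct)
        noise = rng.normal(0.0, cfg.noise_sd_pct, cfg.n_replicates) if cfg.noise_sd_pct else np.zeros(cfg.n_replicates)
        vals = np.clip(mean + noise, 0.0, 100.0)
        for rep, v in enumerate(vals):
            rows.append((m, rep, float(v)))
    df = pd.DataFrame(rows, columns=["peptide_nmol", "replicate", "incorporation_pct"])
    df.attrs["truth"] = cfg.truth()
    return df


def gen_stability(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Synthetic RCP-vs-time stability series per quencher level.

    Returns a DataFrame with columns ``ascorbic_mmol_L, time_min,
    replicate, rcp_pct``; truth parameters in ``.attrs["truth"]``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
    )
    rows = []
    for c in cfg.ascorbic_mmol_L:
        rcp0 = cfg.rcp0_pct.get(c)
        if rcp0 is None:
            # interpolate the baseline for unlisted concentrations
            ks = np.array(sorted(cfg.rcp0_pct))
            rcp0 = float(np.interp(c, ks, [cfg.rcp0_pct[k] for k in ks]))
        k = cfg.decay_rate_per_min(c)
        for t in cfg.time_points_min:
            mean = rcp0 * np.exp(-k * t)
            noise = rng.normal(0.0, cfg.noise_sd_pct, cfg.n_replicates) if cfg.noise_sd_pct else np.zeros(cfg.n_replicates)
            vals = np.clip(mean + noise, 0.0, 100.0)
            for rep, v in enumerate(vals):
                rows.append((c, t, rep, float(v)))
    df = pd.DataFrame(rows, columns=["ascorbic_mmol_L", "time_min", "replicate", "rcp_pct"])
    df.attrs["truth"] = cfg.truth()
    return df
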