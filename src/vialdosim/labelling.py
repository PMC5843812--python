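"""Radiolabelling chemistry calculators.

Specific-activity arithmetic, recipe osmolarity and dilution, logistic
incorporation-curve fitting, the ascorbic-acid requirement rule and
radiochemical-purity (RCP) threshold checks for ²¹³Bi-DOTA-peptide
labelling reactions.

Units: concentrations are mol/L internally; volumes μL; peptide amounts
nmol; activities MBq; incorporation and RCP on the percent scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RecipeComponent",
    "LabellingRecipe",
    "IncorporationFit",
    "StabilitySeries",
    "FitError",
    "AVOGADRO",
    "max_specific_activity",
    "achievable_sa",
    "osmolarity",
    "dilute",
    "logistic",
    "fit_incorporation",
    "minimum_peptide_for_incorporation",
    "required_ascorbic",
    "rcp_pass",
    "standard_recipe",
    "optimized_recipe",
    "recipe_to_csv",
    "recipe_from_csv",
]

AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# recipes


@dataclass
class RecipeComponent:
    """One solute: stock concentration and added volume fix the final
    concentration (stock·volume/total); ``ions_per_unit`` counts the
    osmotically active particles per formula unit (2 for fully
    dissociating 1:1 salts such as NaI and HCl, 1 otherwise)."""

    name: str
    stock_conc_M: float
    volume_uL: float
    ions_per_unit: int = 1

    def final_conc_M(self, total_volume_uL: float) -> float:
        return self.stock_conc_M * self.volume_uL / total_volume_uL


@dataclass
class LabellingRecipe:
    components: list[RecipeComponent]
    total_volume_uL: float
    peptide_nmol: float = 0.0
    activity_MBq: float = 0.0

    def __post_init__(self) -> None:
        for c in self.components:
            if c.volume_uL > self.total_volume_uL + 1e-9:
                raise ValueError(f"{c.name}: component volume exceeds total volume")
            if c.stock_conc_M < 0:
                raise ValueError(f"{c.name}: negative concentration")

    def final_concentrations_M(self) -> dict[str, float]:
        return {
            c.name: c.final_conc_M(self.total_volume_uL) for c in self.components
        }


def standard_recipe(peptide_nmol: float = 7.0, activity_MBq: float = 100.0) -> LabellingRecipe:
    """Standard ²¹³Bi-DOTATATE protocol: 0.34 M TRIS and 71 mM ascorbic
    acid (final), 600 μL generator eluate (0.1 M NaI / 0.1 M HCl) in a
    final volume of 800 μL; DTPA 50 nmol added post-labelling."""
    return LabellingRecipe(
        components=[
            RecipeComponent("TRIS", 0.34, 800.0, 1),
            RecipeComponent("ascorbic acid", 0.071, 800.0, 1),
            RecipeComponent("NaI", 0.1, 600.0, 2),
            RecipeComponent("HCl", 0.1, 600.0, 2),
            RecipeComponent("DTPA", 50e-9 / 800e-6, 800.0, 1),
        ],
        total_volume_uL=800.0,
        peptide_nmol=peptide_nmol,
        activity_MBq=activity_MBq,
    )


def optimized_recipe(peptide_nmol: float = 3.5, activity_MBq: float = 100.0) -> LabellingRecipe:
    """Optimized preclinical protocol: 0.15 M TRIS, 2.6 mM ascorbic acid,
    same eluate, 800 μL."""
    return LabellingRecipe(
        components=[
            RecipeComponent("TRIS", 0.15, 800.0, 1),
            RecipeComponent("ascorbic acid", 0.0026, 800.0, 1),
            RecipeComponent("NaI", 0.1, 600.0, 2),
            RecipeComponent("HCl", 0.1, 600.0, 2),
            RecipeComponent("DTPA", 50e-9 / 800e-6, 800.0, 1),
        ],
        total_volume_uL=800.0,
        peptide_nmol=peptide_nmol,
        activity_MBq=activity_MBq,
    )


def osmolarity(recipe: LabellingRecipe, include: tuple[str, ...] | None = None) -> float:
    """Calculated osmolarity (Osmol/L): Σ final concentration × ions per
    formula unit over the buffer, quencher and eluate salts.  The peptide
    and DTPA contribute ≲ 1e−4 Osmol/L and are excluded by default."""
    skip = {"DTPA"} if include is None else set()
    total = 0.0
    for c in recipe.components:
        if include is not None and c.name not in include:
            continue
        if include is None and c.name in skip:
            continue
        total += c.final_conc_M(recipe.total_volume_uL) * c.ions_per_unit
    return total


def dilute(
    recipe: LabellingRecipe, aliquot_uL: float, final_volume_uL: float
) -> dict[str, float]:
    """Concentrations (mol/L) after diluting an aliquot of the reaction
    into a larger final volume (e.g. into cell-culture medium)."""
    if aliquot_uL > final_volume_uL:
        raise ValueError("aliquot cannot exceed the final volume")
    f = aliquot_uL / final_volume_uL
    return {name: conc * f for name, conc in recipe.final_concentrations_M().items()}


def recipe_to_csv(recipe: LabellingRecipe, path) -> None:
    """Write a recipe as delimited text.

    Columns: ``name, stock_conc_M, volume_uL, ions_per_unit,
    total_volume_uL, peptide_nmol, activity_MBq`` (the last three are
    recipe-level values repeated on every row).
    """
    rows = [
        {
            "name": c.name,
            "stock_conc_M": c.stock_conc_M,
            "volume_uL": c.volume_uL,
            "ions_per_unit": c.ions_per_unit,
            "total_volume_uL": recipe.total_volume_uL,
            "peptide_nmol": recipe.peptide_nmol,
            "activity_MBq": recipe.activity_MBq,
        }
        for c in recipe.components
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def recipe_from_csv(path) -> LabellingRecipe:
    """Read a recipe written by :func:`recipe_to_csv`."""
    df = pd.read_csv(path)
    components = [
        RecipeComponent(
            name=str(r["name"]),
            stock_conc_M=float(r["stock_conc_M"]),
            volume_uL=float(r["volume_uL"]),
            ions_per_unit=int(r["ions_per_unit"]),
        )
        for _, r in df.iterrows()
    ]
    first = df.iloc[0]
    return LabellingRecipe(
        components=components,
        total_volume_uL=float(first["total_volume_uL"]),
        peptide_nmol=float(first["peptide_nmol"]),
        activity_MBq=float(first["activity_MBq"]),
    )


# ---------------------------------------------------------------------------
# specific activity


def max_specific_activity(half_life_s: float) -> float:
    """Carrier-free specific activity in GBq/nmol: λ·N_A·1e−9 atoms per
    nmol, one radionuclide atom per chelator at mole ratio 1."""
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    lam = math.log(2.0) / half_life_s
    return lam * AVOGADRO * 1e-9 / 1e9  # Bq/nmol → GBq/nmol


def achievable_sa(max_sa_GBq_nmol: float, mole_ratio: float) -> float:
    """Specific activity at a metal:chelator mole ratio ≤ 1."""
    if not 0.0 <= mole_ratio <= 1.0:
        raise ValueError("mole ratio must be in [0, 1]")
    return max_sa_GBq_nmol * mole_ratio


# ---------------------------------------------------------------------------
# incorporation fitting


class FitError(RuntimeError):
    """Raised when the incorporation fit cannot converge; carries
    diagnostics in ``.details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


@dataclass
class IncorporationFit:
    """Logistic incorporation curve I(m) = asymptote / (1 + e^{−(m−m₅₀)/s})."""

    m50_nmol: float
    slope_nmol: float
    asymptote_pct: float
    se_m50: float
    se_slope: float
    se_asymptote: float
    residual_sd_pct: float
    n_points: int
    asymptote_fixed: bool = False

    def predict(self, m):
        return logistic(np.asarray(m, dtype=float), self.m50_nmol, self.slope_nmol, self.asymptote_pct)


def logistic(m, m50, s, asymptote=100.0):
    return asymptote / (1.0 + np.exp(-(np.asarray(m, dtype=float) - m50) / s))


def fit_incorporation(
    peptide_amounts_nmol,
    incorporation_pct,
    fix_asymptote: float | None = None,
) -> IncorporationFit:
    """Least-squares logistic fit of incorporation yield vs peptide amount.

    The asymptote is a free parameter bounded at 100 %; with fewer than 5
    distinct amounts it is fixed to the mean of the plateau points (the
    upper half of the amount range), which stabilizes the 3-parameter fit
    on sparse designs.  Raises :class:`FitError` with diagnostics when
    the data do not describe a rising sigmoid.
    """
    m = np.asarray(peptide_amounts_nmol, dtype=float)
    y = np.asarray(incorporation_pct, dtype=float)
    if m.size != y.size or m.size < 4:
        raise ValueError("need >= 4 (amount, incorporation) points")
    order = np.argsort(m)
    m, y = m[order], y[order]

    # reject clearly non-increasing data before attempting a fit
    uniq = np.unique(m)
    means = np.array([y[m == u].mean() for u in uniq])
    if means[-1] <= means[0]:
        raise FitError(
            "incorporation does not increase with peptide amount; "
            "a rising logistic cannot describe these data",
            details={"amount_means": dict(zip(uniq.tolist(), means.tolist()))},
        )

    m50_guess = float(np.interp(0.5 * (means.max() + means.min()), means, uniq))
    s_guess = max(0.05 * (uniq[-1] - uniq[0]), 1e-3)
    plateau = means[uniq >= np.median(uniq)].mean()

    fixed = fix_asymptote
    if fixed is None and uniq.size < 5:
        fixed = float(min(plateau, 100.0))

    try:
        if fixed is not None:
            popt, pcov = curve_fit(
                lambda mm, m50, s: logistic(mm, m50, s, fixed),
                m, y, p0=[m50_guess, s_guess],
                bounds=([uniq[0] - 5, 1e-4], [uniq[-1] + 5, uniq[-1]]),
                maxfev=20000,
            )
            m50, s = popt
            a, se_a = fixed, 0.0
            perr = np.sqrt(np.diag(pcov))
            se_m50, se_s = perr
        else:
            popt, pcov = curve_fit(
                logistic, m, y, p0=[m50_guess, s_guess, min(plateau, 100.0)],
                bounds=([uniq[0] - 5, 1e-4, 1.0], [uniq[-1] + 5, uniq[-1], 100.0]),
                maxfev=20000,
            )
            m50, s, a = popt
            perr = np.sqrt(np.diag(pcov))
            se_m50, se_s, se_a = perr
    except RuntimeError as exc:
        raise FitError(f"logistic fit failed to converge: {exc}") from exc

    resid = y - logistic(m, m50, s, a)
    dof = max(m.size - (2 if fixed is not None else 3), 1)
    return IncorporationFit(
        m50_nmol=float(m50),
        slope_nmol=float(s),
        asymptote_pct=float(a),
        se_m50=float(se_m50),
        se_slope=float(se_s),
        se_asymptote=float(se_a),
        residual_sd_pct=float(np.sqrt((resid**2).sum() / dof)),
        n_points=int(m.size),
        asymptote_fixed=fixed is not None,
    )


def minimum_peptide_for_incorporation(
    fit: IncorporationFit, target_pct: float
) -> float:
    """Smallest peptide amount (nmol) whose predicted incorporation meets
    the target; infinite if the asymptote is below the target."""
    if target_pct >= fit.asymptote_pct:
        return math.inf
    frac = target_pct / fit.asymptote_pct
    return fit.m50_nmol - fit.slope_nmol * math.log(1.0 / frac - 1.0)


# ---------------------------------------------------------------------------
# ascorbic-acid requirement and RCP checks

ASCORBIC_ANCHOR_MMOL_L = 0.9
ASCORBIC_ANCHOR_DOSE_GY = 200.0
ASCORBIC_ANCHOR_VOLUME_UL = 800.0


def required_ascorbic(dose_Gy: float, volume_uL: float = 800.0) -> dict:
    """Minimum ascorbic-acid concentration (mmol/L) protecting the peptide.

    Empirical anchor: 0.9 mmol/L suffices for ~200 Gy absorbed in 800 μL.
    Doses up to the anchor (scaled to the actual volume, since the
    radical load tracks energy per unit volume) return the anchor value;
    above it the requirement extrapolates linearly in dose and the result
    carries ``extrapolated=True`` — the linear scaling is a modelling
    choice, not a measured calibration.
    """
    if dose_Gy < 0:
        raise ValueError("dose must be non-negative")
    if dose_Gy == 0:
        return {"mmol_per_L": 0.0, "extrapolated": False, "anchor_mmol_per_L": ASCORBIC_ANCHOR_MMOL_L}
    anchor_dose = ASCORBIC_ANCHOR_DOSE_GY * ASCORBIC_ANCHOR_VOLUME_UL / volume_uL
    scale = dose_Gy / anchor_dose
    if scale <= 1.0:
        return {
            "mmol_per_L": ASCORBIC_ANCHOR_MMOL_L,
            "extrapolated": False,
            "anchor_mmol_per_L": ASCORBIC_ANCHOR_MMOL_L,
        }
    return {
        "mmol_per_L": ASCORBIC_ANCHOR_MMOL_L * scale,
        "extrapolated": True,
        "anchor_mmol_per_L": ASCORBIC_ANCHOR_MMOL_L,
    }


@dataclass
class StabilitySeries:
    """RCP (%) vs time (min) at one ascorbic-acid concentration."""

    time_min: np.ndarray
    rcp_pct: np.ndarray
    ascorbic_mmol_L: float

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.rcp_pct = np.asarray(self.rcp_pct, dtype=float)
        if self.time_min.size != self.rcp_pct.size or self.time_min.size == 0:
            raise ValueError("time and RCP arrays must be non-empty and equal length")
        if np.any((self.rcp_pct < 0) | (self.rcp_pct > 100)):
            raise ValueError("RCP values must lie in [0, 100] %")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ascorbic_mmol_L": self.ascorbic_mmol_L,
                "time_min": self.time_min,
                "rcp_pct": self.rcp_pct,
            }
        )


def rcp_pass(
    series: StabilitySeries, threshold_pct: float = 85.0, horizon_min: float = 120.0
) -> tuple[bool, dict]:
    """True iff every RCP value within the horizon meets the threshold;
    the summary lists the violating (time, RCP) pairs."""
    mask = series.time_min <= horizon_min
    if not np.any(mask):
        raise ValueError("no measurements inside the horizon window")
    t, r = series.time_min[mask], series.rcp_pct[mask]
    bad = r < threshold_pct
    summary = {
        "threshold_pct": threshold_pct,
        "horizon_min": horizon_min,
        "n_checked": int(mask.sum()),
        "min_rcp_pct": float(r.min()),
        "violations": [
            {"time_min": float(tt), "rcp_pct": float(rr)} for tt, rr in zip(t[bad], r[bad])
        ],
    }
    return bool(not bad.any()), summary
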