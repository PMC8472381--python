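"""Buoyant-density modelling of DNA across an isopycnic CsCl gradient.

DNA of a single taxon equilibrates around its buoyant density, so its mass
profile over the collected fractions is modelled as a Gaussian
``A * exp(-(x - mu)^2 / (2 sigma^2))`` in density ``x``; the fitted mean
``mu`` is the best estimate of the taxon's buoyant density in that bottle.
Fully replacing carbon with the heavy isotope raises DNA buoyant density by
about 0.036 g/mL, so the shift between the labeled and the control bottle,
divided by 0.036, is the atom fraction of heavy carbon in the taxon's DNA.

When a taxon is too sparse in the control bottle for a reliable fit, its
unlabeled density can instead be predicted from GC content with the
Schildkraut relation rho = 1.660 + 0.098*GC (g/mL), since GC also raises
buoyant density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GradientConfig",
    "DensityFit",
    "LabelingResult",
    "DELTA_RHO_FULL_LABEL",
    "asv_dna_per_fraction",
    "fit_density_gaussian",
    "theoretical_density",
    "labeling_level",
    "labeling_table",
]

logger = logging.getLogger(__name__)

#: buoyant-density increase (g/mL) of DNA at 100% heavy-carbon labeling
DELTA_RHO_FULL_LABEL = 0.036

#: plausible CsCl gradient density window (g/mL)
DENSITY_RANGE = (1.60, 1.85)


@dataclass(frozen=True)
class GradientConfig:
    """Thresholds for density fitting and labeling calls.

    min_fit_points:
        Minimum number of fractions with positive DNA mass for a Gaussian
        fit to be attempted.
    min_r2:
        Fits below this R² are rejected (control bottle: triggers the GC
        fallback; labeled bottle: excludes the ASV from the significant set).
    min_labeling:
        Atom-fraction threshold for calling an ASV significantly labeled.
    indirect_below:
        Labeling below this level is flagged as possibly arising from
        cross-feeding on labeled metabolites rather than direct consumption.
    delta_rho_full:
        Density shift (g/mL) corresponding to 100% labeling.
    """

    min_fit_points: int = 4
    min_r2: float = 0.8
    min_labeling: float = 0.10
    indirect_below: float = 0.25
    delta_rho_full: float = DELTA_RHO_FULL_LABEL


@dataclass(frozen=True)
class DensityFit:
    """Fitted (or theoretical) buoyant density of one ASV in one bottle."""

    asv_id: str
    bottle: str
    mean_density: float
    spread: float
    amplitude: float
    r_squared: float
    source: str = "fitted"  # "fitted" | "theoretical"
    n_points: int = 0


@dataclass(frozen=True)
class LabelingResult:
    """Atom-fraction labeling of one ASV from its two-bottle density shift."""

    asv_id: str
    density_12c: float
    density_13c: float
    labeling: float
    flag: str = "none"  # "none" | "possibly_indirect" | "insufficient_data"
    significant: bool = field(default=False, compare=False)


def asv_dna_per_fraction(
    dna_total_ng: float, asv_reads: int, total_reads: int
) -> float:
    """Allocate a fraction's DNA mass to one ASV by its read share."""
    if total_reads <= 0:
        raise ValueError("fraction has no reads; it contributes no point")
    if dna_total_ng < 0 or asv_reads < 0:
        raise ValueError("mass and reads must be non-negative")
    return dna_total_ng * asv_reads / total_reads


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_density_gaussian(
    densities,
    masses,
    *,
    asv_id: str = "",
    bottle: str = "",
    min_fit_points: int = 4,
) -> DensityFit | None:
    """Least-squares Gaussian fit of DNA mass versus fraction density.

    All supplied points (including zero-mass fractions) constrain the fit,
    but at least ``min_fit_points`` fractions must carry positive mass.
    The mean is initialised at the mass-weighted mean density and bounded to
    the observed density range; the spread is initialised at the
    mass-weighted standard deviation. R² is reported unclamped (it can be
    negative for fits worse than a flat line).

    Returns ``None`` when there are too few positive points or the
    optimiser fails — the caller decides on a fallback.
    """
    x = np.asarray(densities, dtype=float)
    y = np.asarray(masses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("densities and masses must be 1-D arrays of equal length")
    positive = int(np.sum(y > 0))
    if positive < min_fit_points:
        return None

    w = y.clip(min=0)
    mu0 = float(np.average(x, weights=w))
    sigma0 = float(np.sqrt(np.average((x - mu0) ** 2, weights=w)))
    span = float(x.max() - x.min()) or 1e-3
    sigma0 = min(max(sigma0, 1e-4), span)
    a0 = float(y.max())

    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=(a0, mu0, sigma0),
            bounds=((0.0, x.min(), 1e-5), (np.inf, x.max(), span)),
            maxfev=10_000,
        )
    except RuntimeError:
        return None

    amplitude, mu, sigma = (float(v) for v in popt)
    resid = y - _gaussian(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DensityFit(
        asv_id=asv_id,
        bottle=bottle,
        mean_density=mu,
        spread=sigma,
        amplitude=amplitude,
        r_squared=r2,
        source="fitted",
        n_points=len(x),
    )


def theoretical_density(gc_fraction: float) -> float:
    """Buoyant density (g/mL) of unlabeled DNA from its GC content.

    Schildkraut relation: rho = 1.660 + 0.098 * GC.
    """
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError(f"GC fraction must be in [0, 1], got {gc_fraction!r}")
    return 1.660 + 0.098 * gc_fraction


def labeling_level(
    density_12c: float,
    density_13c: float,
    *,
    asv_id: str = "",
    delta_rho_full: float = DELTA_RHO_FULL_LABEL,
    indirect_below: float = 0.25,
) -> LabelingResult:
    """Atom-fraction labeling from the control→labeled density shift.

    ``clamp((rho_13C - rho_12C) / delta_rho_full, 0, 1)``. Levels below
    ``indirect_below`` are flagged: weak shifts can come from cross-feeding
    on labeled breakdown products rather than direct substrate consumption.
    """
    if not (np.isfinite(density_12c) and np.isfinite(density_13c)):
        raise ValueError("densities must be finite")
    raw = (density_13c - density_12c) / delta_rho_full
    labeling = min(max(raw, 0.0), 1.0)
    flag = "possibly_indirect" if labeling < indirect_below else "none"
    return LabelingResult(
        asv_id=asv_id,
        density_12c=density_12c,
        density_13c=density_13c,
        labeling=labeling,
        flag=flag,
    )


def _points_for(
    asv_id: str, bottle: str, fractions: pd.DataFrame, fraction_counts: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(density, allocated DNA ng) points for one ASV in one bottle."""
    frs = fractions.loc[fractions["bottle"] == bottle]
    cts = fraction_counts.loc[fraction_counts["bottle"] == bottle]
    totals = cts.groupby("fraction_id")["reads"].sum()
    own = (
        cts.loc[cts["asv_id"] == asv_id]
        .set_index("fraction_id")["reads"]
        .astype(int)
    )
    xs, ys = [], []
    for row in frs.itertuples(index=False):
        total = int(totals.get(row.fraction_id, 0))
        if total <= 0:
            continue  # a fraction with no reads contributes no point
        reads = int(own.get(row.fraction_id, 0))
        xs.append(float(row.density_g_per_ml))
        ys.append(asv_dna_per_fraction(float(row.dna_ng), reads, total))
    return np.asarray(xs), np.asarray(ys)


def labeling_table(
    fractions: pd.DataFrame,
    fraction_counts: pd.DataFrame,
    *,
    gc_of: dict[str, float] | None = None,
    config: GradientConfig = GradientConfig(),
    control_bottle: str = "c12",
    labeled_bottle: str = "c13",
) -> pd.DataFrame:
    """Per-ASV buoyant densities and labeling levels from fraction data.

    For each ASV appearing in ``fraction_counts``, fits a Gaussian in both
    bottles. A failed or poor (R² < ``config.min_r2``) control-bottle fit
    degrades to the GC-based theoretical density when ``gc_of`` supplies a
    GC fraction, else the ASV is flagged ``insufficient_data``. A failed
    labeled-bottle fit always flags ``insufficient_data`` (there is no
    theoretical stand-in for an unknown labeling level).

    Returns a DataFrame indexed by ``asv_id`` with the fitted densities,
    spreads, R² values, density source, labeling, flag, and whether the ASV
    passes the significance rule (labeling ≥ ``config.min_labeling`` and
    labeled-bottle R² ≥ ``config.min_r2``).
    """
    rows = []
    for asv_id in sorted(fraction_counts["asv_id"].unique()):
        fits: dict[str, DensityFit | None] = {}
        for bottle in (control_bottle, labeled_bottle):
            x, y = _points_for(asv_id, bottle, fractions, fraction_counts)
            fits[bottle] = (
                fit_density_gaussian(
                    x, y, asv_id=asv_id, bottle=bottle,
                    min_fit_points=config.min_fit_points,
                )
                if len(x)
                else None
            )

        fit12, fit13 = fits[control_bottle], fits[labeled_bottle]
        source_12c = "fitted"
        if fit12 is None or fit12.r_squared < config.min_r2:
            gc = gc_of.get(asv_id) if gc_of else None
            if gc is not None:
                fit12 = DensityFit(
                    asv_id=asv_id,
                    bottle=control_bottle,
                    mean_density=theoretical_density(gc),
                    spread=float("nan"),
                    amplitude=float("nan"),
                    r_squared=fit12.r_squared if fit12 is not None else float("nan"),
                    source="theoretical",
                )
                source_12c = "theoretical"
                logger.info("ASV %s: control-bottle fit degraded to GC density", asv_id)
            else:
                fit12 = None

        rec: dict[str, object] = {"asv_id": asv_id, "density_source_12c": source_12c}
        if fit12 is None or fit13 is None:
            rec.update(
                density_12c=float("nan"),
                density_13c=float("nan"),
                labeling=float("nan"),
                flag="insufficient_data",
                significant=False,
                r2_12c=fit12.r_squared if fit12 else float("nan"),
                r2_13c=fit13.r_squared if fit13 else float("nan"),
            )
        else:
            res = labeling_level(
                fit12.mean_density,
                fit13.mean_density,
                asv_id=asv_id,
                delta_rho_full=config.delta_rho_full,
                indirect_below=config.indirect_below,
            )
            rec.update(
                density_12c=fit12.mean_density,
                density_13c=fit13.mean_density,
                labeling=res.labeling,
                flag=res.flag,
                significant=(
                    res.labeling >= config.min_labeling
                    and fit13.r_squared >= config.min_r2
                ),
                r2_12c=fit12.r_squared,
                r2_13c=fit13.r_squared,
            )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("asv_id")
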