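"""Seed-reproducible synthetic SIP experiments with known ground truth.

The generator emulates a two-bottle isotope-probing experiment: a labeled
bottle fed heavy-carbon phage particles and an unlabeled control. Each
taxon's DNA is normally distributed over buoyant density; its unlabeled
peak position follows the Schildkraut GC relation, and in the labeled
bottle the peak is shifted by 0.036 g/mL times its true atom-fraction
labeling. Observations are generated through the same measurement layers
the analysis assumes: log-normal multiplicative noise on per-fraction DNA
mass (fluorometry), multinomial read sampling within each fraction and
each bulk sample (amplicon sequencing), and Gaussian noise on qPCR cycle
thresholds. Default parameters mirror the real experiment's printed
community: nine labeled taxa with the study's labeling levels, initial and
final abundance shares, a 9.78e7 → 2.47e8 total 16S copy trajectory, and a
3e5-copy spiked standard.

The generator writes exactly the file dialects the pipeline reads, so it
doubles as living format documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .carbon import CarbonConstants, phage_carbon_pool

__all__ = ["SimulationConfig", "SyntheticExperiment", "simulate_experiment", "worked_example_fixture"]

# Printed community of the real experiment: nine labeled taxa.
_LABELED_LEVELS = (0.85, 0.95, 0.10, 0.14, 0.71, 0.19, 0.49, 0.16, 0.23)
_LABELED_INITIAL_READS = (0, 0, 148, 132, 197, 123, 0, 46, 53)  # of 3748
_LABELED_FINAL_READS = (303, 1545, 37, 62, 52, 55, 55, 41, 55)  # of 3578
_LABELED_COPY_NUMBERS = (10, 10, 4, 4, 1, 2, 1, 2, 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic two-bottle SIP experiment.

    Community structure defaults to the real experiment's printed values
    (nine labeled taxa among ``n_asvs``, with its labeling levels, read
    shares, copy numbers and total 16S trajectory). Measurement-noise
    defaults: 10% CV log-normal noise on fraction DNA, 0.1-cycle Gaussian
    noise on qPCR Cts with triplicate wells, multinomial read sampling at
    100,000 reads per gradient fraction and 4,000 per bulk sample.
    """

    n_asvs: int = 50
    n_labeled: int = 9
    n_fractions: int = 12
    density_range: tuple[float, float] = (1.65, 1.78)
    gradient_spread: float = 0.006  # Gaussian sigma of a taxon's DNA, g/mL
    labeling_levels: tuple[float, ...] = _LABELED_LEVELS
    labeled_initial_shares: tuple[float, ...] = tuple(
        r / 3748 for r in _LABELED_INITIAL_READS
    )
    labeled_final_shares: tuple[float, ...] = tuple(
        r / 3578 for r in _LABELED_FINAL_READS
    )
    labeled_copy_numbers: tuple[float, ...] = _LABELED_COPY_NUMBERS
    initial_total_copies: float = 9.78e7
    final_total_copies: float = 2.47e8  # sampling-corrected end point
    gc_range: tuple[float, float] = (0.35, 0.65)
    unlabeled_fold_jitter_sd: float = 0.3  # log-sd of unlabeled growth folds
    read_depth_per_fraction: int = 100_000
    bulk_read_depth: int = 4_000
    total_dna_ng: float = 400.0  # DNA recovered across one bottle's gradient
    dna_noise_cv: float = 0.10
    ct_noise_sd: float = 0.1
    qpcr_replicates: int = 3
    efficiency_range: tuple[float, float] = (0.79, 0.85)
    spike_copies: int = 300_000
    bottle_volume_ul: float = 5200.0
    volume_removed_ul: float = 240.0
    n_phages_13c: float = 2.28e10
    initial_pfu: tuple[float, float] = (2.8e10, 2.24e10)  # (c12, c13) per bottle
    pfu_times_min: tuple[float, ...] = (0.0, 24.0, 122.0, 445.0, 1375.0)
    pfu_final_fraction: float = 2e-8  # residual free phages at the last time
    constants: CarbonConstants = field(default_factory=CarbonConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labeled > self.n_asvs:
            raise ValueError("n_labeled cannot exceed n_asvs")
        if len(self.labeling_levels) != self.n_labeled:
            raise ValueError("labeling_levels must have n_labeled entries")
        if self.read_depth_per_fraction <= 0 or self.bulk_read_depth <= 0:
            raise ValueError("read depths must be positive")
        for v in (self.dna_noise_cv, self.ct_noise_sd):
            if v < 0:
                raise ValueError("noise parameters must be non-negative")


@dataclass
class SyntheticExperiment:
    """Generated observable tables plus the ground truth behind them."""

    config: SimulationConfig
    truth: pd.DataFrame  # per-ASV ground truth, indexed by asv_id
    truth_totals: dict  # scalar ground truth (totals, consumed label, ...)
    tables: dict[str, pd.DataFrame]  # qpcr, counts, fractions, fraction_counts, ...
    dna_matrix: dict[str, pd.DataFrame]  # bottle -> (asv x fraction) DNA ng, post-noise

    def write(self, outdir: str | Path) -> Path:
        """Write all observable tables (TSV) plus truth and run config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")
        self.truth.reset_index().to_csv(
            outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g"
        )
        cfg = {
            "spike_copies": self.config.spike_copies,
            "bottle_volume_ul": self.config.bottle_volume_ul,
            "volume_removed_ul": self.config.volume_removed_ul,
            "initial_sample": "initial",
            "final_sample": "final_13c",
            "carbon_per_cell_g": self.config.constants.carbon_per_cell,
            "carbon_per_phage_g": self.config.constants.carbon_per_phage,
            "yield": self.config.constants.yield_,
            "pool_13c_g": self.config.constants.pool_13c,
            "phage_label_purity": self.config.constants.phage_label_purity,
            "seed": self.config.seed,
        }
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return outdir


def _solve_ct(fold: float, ct_target: float, e_std: float, e_target: float) -> float:
    """Standard-assay Ct consistent with a target-over-spike fold.

    Inverts fold = (1+E_std)^Ct_std / (1+E_tgt)^Ct_tgt for Ct_std.
    """
    return (np.log(fold) + ct_target * np.log1p(e_target)) / np.log1p(e_std)


def _qpcr_rows(
    rng: np.random.Generator,
    sample_id: str,
    copies_in_tube: float,
    ct_target_base: float,
    config: SimulationConfig,
) -> list[dict]:
    e_lo, e_hi = config.efficiency_range
    e_std = float(rng.uniform(e_lo, e_hi))
    e_tgt = float(rng.uniform(e_lo, e_hi))
    fold = copies_in_tube / config.spike_copies
    ct_std = _solve_ct(fold, ct_target_base, e_std, e_tgt)
    rows = []
    for _ in range(config.qpcr_replicates):
        rows.append({
            "sample_id": sample_id, "assay": "internal_standard",
            "efficiency_percent": 100 * e_std,
            "ct": ct_std + rng.normal(0.0, config.ct_noise_sd),
        })
        rows.append({
            "sample_id": sample_id, "assay": "target_16s",
            "efficiency_percent": 100 * e_tgt,
            "ct": ct_target_base + rng.normal(0.0, config.ct_noise_sd),
        })
    return rows


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Generate one synthetic experiment under ``config``.

    The same seed always yields byte-identical tables. Per-fraction DNA of
    all taxa sums exactly to the fraction's recorded total (noise is applied
    to taxon masses *before* the total is formed).
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_asvs, config.n_labeled
    asv_ids = [f"asv{i + 1:03d}" for i in range(n)]
    labeled = np.zeros(n, dtype=bool)
    labeled[:k] = True

    # --- community structure -------------------------------------------------
    gc = rng.uniform(*config.gc_range, size=n)
    base_density = 1.660 + 0.098 * gc
    labeling = np.zeros(n)
    labeling[:k] = config.labeling_levels

    init_shares = np.empty(n)
    fin_shares = np.empty(n)
    init_shares[:k] = config.labeled_initial_shares
    fin_shares[:k] = config.labeled_final_shares
    bg = rng.lognormal(0.0, 1.0, size=n - k)
    init_shares[k:] = (1.0 - init_shares[:k].sum()) * bg / bg.sum()
    jitter = rng.lognormal(0.0, config.unlabeled_fold_jitter_sd, size=n - k)
    w = init_shares[k:] * jitter
    fin_shares[k:] = (1.0 - fin_shares[:k].sum()) * w / w.sum()

    init_copies = config.initial_total_copies * init_shares
    fin_copies = config.final_total_copies * fin_shares
    new_copies = np.clip(fin_copies - init_copies, 0.0, None)

    cpn = np.empty(n)
    cpn[:k] = config.labeled_copy_numbers
    cpn[k:] = rng.integers(1, 8, size=n - k).astype(float)
    new_cells = new_copies / cpn

    # Self-consistent pool: the labeled-carbon pool is what the simulated
    # particles actually carry, so truth and estimate share one denominator.
    constants = config.constants.with_pool(
        phage_carbon_pool(config.n_phages_13c, config.constants)
    )
    consumed = new_cells * constants.carbon_per_cell * labeling / constants.yield_
    truth_fraction = float(consumed.sum() / constants.pool_13c)

    truth = pd.DataFrame(
        {
            "labeled": labeled,
            "labeling": labeling,
            "gc_fraction": gc,
            "density_12c": base_density,
            "density_13c": base_density + 0.036 * labeling,
            "initial_copies": init_copies,
            "final_copies": fin_copies,
            "new_copies": new_copies,
            "copies_per_genome": cpn,
            "new_cells": new_cells,
            "consumed_13c_g": consumed,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )

    # --- qPCR (spiked-standard quantification) -------------------------------
    in_bottle_final = config.final_total_copies * (
        (config.bottle_volume_ul - config.volume_removed_ul) / config.bottle_volume_ul
    )
    qpcr = pd.DataFrame(
        _qpcr_rows(rng, "initial", config.initial_total_copies, 13.2, config)
        + _qpcr_rows(rng, "final_13c", in_bottle_final, 14.1, config)
    )

    # --- bulk amplicon counts ------------------------------------------------
    counts_rows = []
    for sample_id, shares in (("initial", init_shares), ("final_13c", fin_shares)):
        reads = rng.multinomial(config.bulk_read_depth, shares / shares.sum())
        counts_rows += [
            {"sample_id": sample_id, "asv_id": a, "reads": int(r)}
            for a, r in zip(asv_ids, reads)
        ]
    counts = pd.DataFrame(counts_rows)

    # --- gradient fractions --------------------------------------------------
    lo, hi = config.density_range
    frac_density = np.linspace(lo, hi, config.n_fractions)
    frac_ids = [f"F{i + 1:02d}" for i in range(config.n_fractions)]
    fractions_rows, fc_rows = [], []
    dna_matrix: dict[str, pd.DataFrame] = {}
    for bottle in ("c12", "c13"):
        mu = base_density + (0.036 * labeling if bottle == "c13" else 0.0)
        # (asv x fraction) Gaussian weights, normalised per ASV over fractions
        wgt = np.exp(
            -((frac_density[None, :] - mu[:, None]) ** 2)
            / (2.0 * config.gradient_spread**2)
        )
        wgt /= wgt.sum(axis=1, keepdims=True)
        mass = config.total_dna_ng * fin_shares[:, None] * wgt
        if config.dna_noise_cv > 0:
            sigma = np.sqrt(np.log1p(config.dna_noise_cv**2))
            mass = mass * rng.lognormal(
                -0.5 * sigma**2, sigma, size=mass.shape
            )
        dna_matrix[bottle] = pd.DataFrame(
            mass, index=pd.Index(asv_ids, name="asv_id"), columns=frac_ids
        )
        totals = mass.sum(axis=0)  # exact conservation by construction
        for j, (fid, d) in enumerate(zip(frac_ids, frac_density)):
            fractions_rows.append({
                "bottle": bottle, "fraction_id": fid,
                "density_g_per_ml": float(d), "dna_ng": float(totals[j]),
            })
            reads = rng.multinomial(
                config.read_depth_per_fraction, mass[:, j] / totals[j]
            )
            fc_rows += [
                {"bottle": bottle, "fraction_id": fid, "asv_id": a, "reads": int(r)}
                for a, r in zip(asv_ids, reads)
            ]
    fractions = pd.DataFrame(fractions_rows)
    fraction_counts = pd.DataFrame(fc_rows)

    # --- taxonomy / copy numbers --------------------------------------------
    taxonomy = pd.DataFrame({
        "asv_id": asv_ids,
        "genus": [f"genus_{a}" for a in asv_ids],
        "gc_fraction": gc,
    })
    copy_numbers = pd.DataFrame({
        "genus": taxonomy["genus"], "copies_per_genome": cpn,
    })

    # --- free-phage decay ----------------------------------------------------
    times = np.asarray(config.pfu_times_min)
    rate = -np.log(config.pfu_final_fraction) / times[-1]
    pfu_rows = []
    for bottle, p0 in zip(("c12", "c13"), config.initial_pfu):
        series = p0 * np.exp(-rate * times)
        noise = np.ones_like(times)
        noise[1:] = rng.lognormal(0.0, 0.2, size=len(times) - 1)
        for t, p in zip(times, series * noise):
            pfu_rows.append({"bottle": bottle, "time_min": float(t), "pfu": float(p)})
    pfu = pd.DataFrame(pfu_rows)

    truth_totals = {
        "initial_total_copies": config.initial_total_copies,
        "final_total_copies": config.final_total_copies,
        "consumed_13c_g": float(consumed.sum()),
        "pool_13c_g": constants.pool_13c,
        "mass_balance_fraction": truth_fraction,
    }
    tables = {
        "qpcr": qpcr,
        "counts": counts,
        "fractions": fractions,
        "fraction_counts": fraction_counts,
        "taxonomy": taxonomy,
        "copy_numbers": copy_numbers,
        "pfu": pfu,
    }
    return SyntheticExperiment(
        config=config, truth=truth, truth_totals=truth_totals,
        tables=tables, dna_matrix=dna_matrix,
    )


def worked_example_fixture() -> dict:
    """The real experiment's printed worked example as pipeline inputs.

    Packages the published qPCR efficiencies/Cts, bulk read counts, genus
    copy numbers and labeling levels of the nine labeled taxa so the
    quantification and carbon chain run end to end from printed numbers.
    Labeling enters directly as a table (the per-fraction raw data behind
    the density fits were not published at fraction resolution).

    Note on the end-point qPCR rows: reproducing the published 783-fold
    growth requires the two final-sample assay *labels* to be swapped
    relative to the printed table (the pairing as printed would imply a
    ~600-fold community collapse, contradicting the measured growth); the
    (efficiency, Ct) pairs themselves are kept intact.

    Each bulk sample includes an ``asv_other`` row aggregating all
    unlabeled taxa so read totals match the published 3748/3578 depths.
    """
    asvs = ["asv1", "asv2", "asv7", "asv9", "asv12", "asv20", "asv21", "asv67", "asv79"]
    genera = [
        "Aeromonas", "Tolumonas", "Rhodocyclaceae_unclassified", "Dechloromonas",
        "PHOS-HE36_unclassified", "Saprospiraceae_unclassified",
        "PHOS-HE36_unclassified", "Ardenticatenales_unclassified", "Haliscomenobacter",
    ]
    initial = list(_LABELED_INITIAL_READS)
    final = list(_LABELED_FINAL_READS)

    qpcr = pd.DataFrame([
        {"sample_id": "initial", "assay": "internal_standard",
         "efficiency_percent": 79.8, "ct": 23.462},
        {"sample_id": "initial", "assay": "target_16s",
         "efficiency_percent": 82.8, "ct": 13.215},
        # final sample: assay labels swapped relative to print (see docstring)
        {"sample_id": "final_13c", "assay": "internal_standard",
         "efficiency_percent": 84.5, "ct": 24.461},
        {"sample_id": "final_13c", "assay": "target_16s",
         "efficiency_percent": 80.1, "ct": 14.133},
    ])

    counts = pd.DataFrame(
        [{"sample_id": "initial", "asv_id": a, "reads": r} for a, r in zip(asvs, initial)]
        + [{"sample_id": "initial", "asv_id": "asv_other", "reads": 3748 - sum(initial)}]
        + [{"sample_id": "final_13c", "asv_id": a, "reads": r} for a, r in zip(asvs, final)]
        + [{"sample_id": "final_13c", "asv_id": "asv_other", "reads": 3578 - sum(final)}]
    )

    taxonomy = pd.DataFrame({
        "asv_id": asvs + ["asv_other"],
        "genus": genera + ["other"],
        "gc_fraction": [float("nan")] * 10,
    })
    copy_numbers = pd.DataFrame({
        "genus": ["Aeromonas", "Tolumonas", "Rhodocyclaceae_unclassified",
                  "Dechloromonas", "PHOS-HE36_unclassified",
                  "Saprospiraceae_unclassified", "Ardenticatenales_unclassified",
                  "Haliscomenobacter", "other"],
        "copies_per_genome": [10, 10, 4, 4, 1, 2, 2, 2, 1],
    })
    labeling = pd.DataFrame({"asv_id": asvs, "labeling": list(_LABELED_LEVELS)})

    pfu = pd.DataFrame([
        {"bottle": "c12", "time_min": 0, "pfu": 2.8e10},
        {"bottle": "c12", "time_min": 24, "pfu": 5.2e8},
        {"bottle": "c12", "time_min": 122, "pfu": 2.6e7},
        {"bottle": "c12", "time_min": 445, "pfu": 3.2e7},
        {"bottle": "c12", "time_min": 1375, "pfu": 5e2},
        {"bottle": "c13", "time_min": 0, "pfu": 2.2e10},
        {"bottle": "c13", "time_min": 24, "pfu": 9.4e8},
        {"bottle": "c13", "time_min": 122, "pfu": 4.1e8},
        {"bottle": "c13", "time_min": 445, "pfu": 3.3e8},
        {"bottle": "c13", "time_min": 1375, "pfu": 5.7e5},
    ])

    return {
        "qpcr": qpcr,
        "counts": counts,
        "taxonomy": taxonomy,
        "copy_numbers": copy_numbers,
        "labeling": labeling,
        "pfu": pfu,
        "pfu_references": {"c12": 2.8e10, "c13": 2.24e10},
        "spike_copies": 300_000,
        "bottle_volume_ul": 5200.0,
        "volume_removed_ul": 240.0,
        "initial_sample": "initial",
        "final_sample": "final_13c",
        "constants": CarbonConstants(),
    }
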