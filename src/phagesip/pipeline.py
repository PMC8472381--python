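"""End-to-end orchestration: spike-in census → growth → labeling → ledger.

``run_pipeline`` chains the stages on validated input tables and writes a
mass-balance report mirroring the per-taxon bookkeeping (new 16S copies,
cells, carbon, heavy carbon, substrate drawn, share of the labeled pool)
plus per-stage intermediates so every reported number can be audited. The
labeling stage runs either from gradient fraction data (Gaussian density
fits) or from a directly supplied labeling table.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .carbon import CarbonConstants, mass_balance_table
from .community import growth_table, total_growth_fold
from .gradient import GradientConfig, labeling_table
from .phage_assay import PfuObservation, log_reduction, percent_remaining
from .quantify import QpcrMeasurement, SpikeStandard, quantify_sample

__all__ = ["RunConfig", "MassBalanceReport", "PipelineError", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message starts with the stage name in brackets."""


@dataclass
class RunConfig:
    """Paths, constants and thresholds of one pipeline run.

    ``labeling_source`` selects how atom fractions are obtained:
    ``"gradient"`` fits per-taxon density curves from ``fractions`` and
    ``fraction_counts``; ``"table"`` reads them from ``labeling``.
    """

    qpcr: str | Path
    counts: str | Path
    copy_numbers: str | Path | None = None
    taxonomy: str | Path | None = None
    fractions: str | Path | None = None
    fraction_counts: str | Path | None = None
    labeling: str | Path | None = None
    pfu: str | Path | None = None
    labeling_source: str = "gradient"  # "gradient" | "table"
    initial_sample: str = "initial"
    final_sample: str = "final_13c"
    spike_copies: int = 300_000
    bottle_volume_ul: float = 5200.0
    volume_removed_ul: float = 240.0
    pfu_references: dict[str, float] = field(default_factory=dict)
    constants: CarbonConstants = field(default_factory=CarbonConstants)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.labeling_source not in ("gradient", "table"):
            raise ValueError("labeling_source must be 'gradient' or 'table'")
        if self.labeling_source == "table" and self.labeling is None:
            raise ValueError("labeling_source='table' requires a labeling path")
        if self.labeling_source == "gradient" and (
            self.fractions is None or self.fraction_counts is None
        ):
            raise ValueError(
                "labeling_source='gradient' requires fractions and fraction_counts"
            )

    @classmethod
    def from_dir(
        cls,
        indir: str | Path,
        out_dir: str | Path | None = None,
        **overrides,
    ) -> "RunConfig":
        """Build a run from a directory of conventionally named tables.

        Looks for ``qpcr.tsv``, ``counts.tsv``, ``copy_numbers.tsv``,
        ``taxonomy.tsv``, ``fractions.tsv``, ``fraction_counts.tsv``,
        ``labeling.tsv``, ``pfu.tsv`` and an optional ``config.yaml`` of
        scalar keys (spike_copies, bottle_volume_ul, volume_removed_ul,
        sample ids, carbon constants). The labeling source defaults to
        ``"gradient"`` when fraction data exist, else ``"table"``.
        """
        indir = Path(indir)
        paths: dict[str, object] = {}
        for name in ("qpcr", "counts", "copy_numbers", "taxonomy", "fractions",
                     "fraction_counts", "labeling", "pfu"):
            p = indir / f"{name}.tsv"
            if p.exists():
                paths[name] = p
        kwargs: dict[str, object] = dict(paths)
        cfg_path = indir / "config.yaml"
        if cfg_path.exists():
            cfg = pio.read_config(cfg_path)
            for key in ("spike_copies", "bottle_volume_ul", "volume_removed_ul",
                        "initial_sample", "final_sample"):
                if key in cfg:
                    kwargs[key] = cfg[key]
            const_keys = {
                "carbon_per_cell_g": "carbon_per_cell",
                "carbon_per_phage_g": "carbon_per_phage",
                "yield": "yield_",
                "pool_13c_g": "pool_13c",
                "phage_label_purity": "phage_label_purity",
            }
            if any(k in cfg for k in const_keys):
                kwargs["constants"] = CarbonConstants(
                    **{
                        field_name: cfg[key]
                        for key, field_name in const_keys.items()
                        if key in cfg
                    }
                )
        if "labeling_source" not in overrides:
            kwargs["labeling_source"] = (
                "gradient" if "fractions" in paths else "table"
            )
        kwargs.update(overrides)
        kwargs["out_dir"] = out_dir
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass
class MassBalanceReport:
    """Outputs of one run: per-taxon ledger, totals, and provenance."""

    quantification: pd.DataFrame  # per-sample absolute 16S census
    growth: pd.DataFrame  # per-ASV copies/cells ledger
    labeling: pd.DataFrame  # per-ASV densities + atom fractions
    mass_balance: pd.DataFrame  # per-ASV carbon ledger
    total_fraction: float  # summed share of the labeled pool
    pfu_summary: pd.DataFrame | None
    provenance: dict

    @property
    def total_percent(self) -> float:
        return 100.0 * self.total_fraction


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


@_stage("quantify")
def _stage_quantify(config: RunConfig) -> pd.DataFrame:
    qpcr = pio.read_qpcr(config.qpcr)
    spike = SpikeStandard(copies_spiked=config.spike_copies)
    rows = []
    for sample_id, removed in (
        (config.initial_sample, 0.0),
        (config.final_sample, config.volume_removed_ul),
    ):
        sub = qpcr.loc[qpcr["sample_id"] == sample_id]
        if sub.empty:
            raise ValueError(f"no qPCR rows for sample {sample_id!r}")
        meas = {}
        for assay in ("internal_standard", "target_16s"):
            wells = sub.loc[sub["assay"] == assay]
            if wells.empty:
                raise ValueError(f"sample {sample_id!r} lacks a {assay} assay")
            # replicate wells are averaged before the ratio is formed
            meas[assay] = QpcrMeasurement(
                assay_label=assay,
                efficiency=float(wells["efficiency_percent"].mean()) / 100.0,
                ct=float(wells["ct"].mean()),
            )
        quant = quantify_sample(
            meas["internal_standard"], meas["target_16s"], spike,
            volume_removed_ul=removed, bottle_volume_ul=config.bottle_volume_ul,
        )
        rows.append({
            "sample_id": sample_id,
            "fold_over_spike": quant.fold_over_spike,
            "total_16s_copies": quant.total_16s_copies,
            "corrected_for_sampling": quant.corrected_for_sampling,
        })
    return pd.DataFrame(rows).set_index("sample_id")


@_stage("community")
def _stage_growth(config: RunConfig, quant: pd.DataFrame) -> pd.DataFrame:
    counts = pio.read_counts(config.counts)
    genus_of = None
    if config.taxonomy is not None:
        tax = pio.read_taxonomy(config.taxonomy)
        genus_of = dict(zip(tax["asv_id"], tax["genus"]))
    copy_numbers = None
    if config.copy_numbers is not None:
        cn = pio.read_copy_numbers(config.copy_numbers)
        copy_numbers = dict(zip(cn["genus"], cn["copies_per_genome"]))
    return growth_table(
        counts,
        config.initial_sample,
        config.final_sample,
        float(quant.loc[config.initial_sample, "total_16s_copies"]),
        float(quant.loc[config.final_sample, "total_16s_copies"]),
        genus_of=genus_of,
        copy_numbers=copy_numbers,
    )


@_stage("gradient")
def _stage_labeling(config: RunConfig) -> pd.DataFrame:
    if config.labeling_source == "table":
        lab = pio.read_labeling(config.labeling).set_index("asv_id")
        lab["flag"] = [
            "possibly_indirect" if v < config.gradient.indirect_below else "none"
            for v in lab["labeling"]
        ]
        lab["significant"] = lab["labeling"] >= config.gradient.min_labeling
        lab["density_source_12c"] = "table"
        return lab
    fractions = pio.read_fractions(config.fractions)
    fraction_counts = pio.read_fraction_counts(config.fraction_counts)
    gc_of = None
    if config.taxonomy is not None:
        tax = pio.read_taxonomy(config.taxonomy)
        if "gc_fraction" in tax.columns:
            gc_of = {
                a: float(g)
                for a, g in zip(tax["asv_id"], tax["gc_fraction"])
                if pd.notna(g)
            }
    return labeling_table(
        fractions, fraction_counts, gc_of=gc_of, config=config.gradient
    )


@_stage("carbon")
def _stage_carbon(
    config: RunConfig, growth: pd.DataFrame, labeling: pd.DataFrame
) -> pd.DataFrame:
    usable = labeling.loc[labeling["labeling"].notna()]
    return mass_balance_table(
        growth["new_cells"], usable["labeling"], config.constants
    )


@_stage("phage_assay")
def _stage_pfu(config: RunConfig) -> pd.DataFrame | None:
    if config.pfu is None:
        return None
    pfu = pio.read_pfu(config.pfu)
    rows = []
    for bottle, sub in pfu.groupby("bottle"):
        sub = sub.sort_values("time_min")
        obs = [
            PfuObservation(bottle=bottle, time_min=float(t), pfu=float(p))
            for t, p in zip(sub["time_min"], sub["pfu"])
        ]
        reference = config.pfu_references.get(bottle, obs[0].pfu)
        for (t, frac), o in zip(percent_remaining(obs, reference), obs):
            red = log_reduction(obs[0].pfu, o.pfu) if o.pfu > 0 else log_reduction(
                obs[0].pfu, 0.0
            )
            rows.append({
                "bottle": bottle, "time_min": t, "pfu": o.pfu,
                "fraction_remaining": frac,
                "percent_remaining": round(100.0 * frac, 1),
                "log10_reduction_from_t0": red.value,
                "censored": red.censored,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> MassBalanceReport:
    """Execute all stages; optionally write the report to ``config.out_dir``.

    Any stage failure raises :class:`PipelineError` naming the stage;
    partially written outputs are removed.
    """
    quant = _stage_quantify(config)
    growth = _stage_growth(config, quant)
    labeling = _stage_labeling(config)
    ledger = _stage_carbon(config, growth, labeling)
    total = float(ledger["contribution"].sum())
    pfu_summary = _stage_pfu(config)

    provenance = {
        "spike_copies": config.spike_copies,
        "bottle_volume_ul": config.bottle_volume_ul,
        "volume_removed_ul": config.volume_removed_ul,
        "carbon_per_cell_g": config.constants.carbon_per_cell,
        "carbon_per_phage_g": config.constants.carbon_per_phage,
        "yield": config.constants.yield_,
        "pool_13c_g": config.constants.pool_13c,
        "phage_label_purity": config.constants.phage_label_purity,
        "labeling_source": config.labeling_source,
        "min_fit_points": config.gradient.min_fit_points,
        "min_r2": config.gradient.min_r2,
        "min_labeling": config.gradient.min_labeling,
        "indirect_below": config.gradient.indirect_below,
        "delta_rho_full": config.gradient.delta_rho_full,
        "total_growth_fold": total_growth_fold(
            float(quant.iloc[0]["total_16s_copies"]),
            float(quant.iloc[1]["total_16s_copies"]),
        ),
    }
    report = MassBalanceReport(
        quantification=quant,
        growth=growth,
        labeling=labeling,
        mass_balance=ledger,
        total_fraction=total,
        pfu_summary=pfu_summary,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: MassBalanceReport, out_dir: str | Path) -> Path:
    """Write the report tables (TSV) and a provenance log.

    ``mass_balance.tsv`` carries both the full-precision contributions and
    integer-percent display rounding, with a footer total row. On any
    write failure the partially written directory contents are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def emit(df: pd.DataFrame, name: str, index: bool = True) -> None:
            path = out / name
            df.to_csv(path, sep="\t", index=index, float_format="%.10g")
            written.append(path)

        emit(report.quantification, "quantification.tsv")
        emit(report.growth, "growth.tsv")
        emit(report.labeling, "labeling.tsv")
        ledger = report.mass_balance.copy()
        footer = pd.DataFrame(
            {
                "new_cells": [float("nan")],
                "total_carbon": [ledger["total_carbon"].sum()],
                "labeling": [float("nan")],
                "carbon_13": [ledger["carbon_13"].sum()],
                "carbon_13_substrate_needed": [
                    ledger["carbon_13_substrate_needed"].sum()
                ],
                "contribution": [report.total_fraction],
                "contribution_percent": [round(100 * report.total_fraction)],
            },
            index=pd.Index(["TOTAL"], name="asv_id"),
        )
        emit(pd.concat([ledger, footer]), "mass_balance.tsv")
        if report.pfu_summary is not None:
            emit(report.pfu_summary, "pfu_summary.tsv", index=False)
        with open(out / "run.log", "w") as fh:
            for key, value in report.provenance.items():
                fh.write(f"{key}\t{value}\n")
        written.append(out / "run.log")
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        if out.exists() and not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        raise
    return out
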