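"""End-to-end orchestration: screen -> remove -> diversity -> compare.

A :class:`RunConfig` either points at a count table + metadata on disk,
requests a simulated data set, or supplies a percent-abundance block
(abundance-only mode, for worked examples printed without counts — only the
screening and shared-burden stages run there). All stage outputs are TSVs in
the output directory plus a ``report.md`` summary and a ``runlog.json`` with
the seed, config and stage shapes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comparison import (
    DEFAULT_TREATMENT_ORDER,
    compare_treatments,
    comparison_table,
)
from .diversity import METRICS, alpha_diversity, distance_matrix
from .errors import MetadataError, SpecError
from .prevalence import prevalence_results, prevalence_table
from .removal import apply_treatment
from .screening import (
    AbundanceProfile,
    TreatmentSpec,
    classify_threshold,
    round_half_up,
    screening_report,
    shared_contaminant_summary,
)
from .synthetic import GeneratorConfig, generate
from .table_ops import (
    NormalizationConfig,
    SampleMetadata,
    filter_singletons,
    read_feature_table,
    subsample_to_depth,
)

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("richness_S", "shannon_H", "pielou_J")


@dataclass
class RunConfig:
    """Pipeline settings; exactly one input mode must be set."""

    feature_table: str | None = None     # TSV counts
    metadata: str | None = None          # TSV sample metadata
    simulate: dict | None = None         # GeneratorConfig overrides
    abundance_blocks: str | None = None  # percent TSV (abundance-only mode)

    taus: tuple = (1.0, 5.0, 10.0)
    treatments: tuple = DEFAULT_TREATMENT_ORDER
    p_stars: tuple = (0.1, 0.5)
    alpha: float = 0.05
    seed: int = 0
    filter_singletons: bool = True
    normalize: bool = False
    depth: int = 25_000
    drop_below_depth: bool = True
    outdir: str = "results/run"

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SpecError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        modes = [m for m in (cfg.feature_table, cfg.simulate, cfg.abundance_blocks)
                 if m is not None]
        if len(modes) != 1:
            raise SpecError(
                "exactly one of feature_table, simulate, abundance_blocks required")
        if cfg.feature_table is not None and cfg.metadata is None:
            raise SpecError("feature_table input requires metadata")
        if not cfg.treatments:
            raise SpecError("at least one treatment required")
        for t in cfg.taus:
            if t <= 0:
                raise SpecError("taus must be positive")
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_mapping(data)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def _abundance_only_run(cfg: RunConfig, outdir: Path, log: dict) -> dict:
    df = pd.read_csv(cfg.abundance_blocks, sep="\t")
    if "dataset" not in df.columns or "feature_id" not in df.columns \
            or "control" not in df.columns:
        raise SpecError("abundance blocks need dataset, feature_id, control columns")
    tissue_cols = [c for c in df.columns
                   if c not in ("dataset", "feature_id", "control")]
    rows = []
    for ds, grp in df.groupby("dataset", sort=False):
        grp = grp.set_index("feature_id")
        ctrl = AbundanceProfile.from_percentages(grp["control"], f"{ds}:control")
        for tissue in tissue_cols:
            col = grp[tissue]
            if col.isna().all():
                continue
            prof = AbundanceProfile.from_percentages(col, f"{ds}:{tissue}")
            for tau in sorted(cfg.taus):
                summ = shared_contaminant_summary(classify_threshold(ctrl, tau), prof)
                rows.append({
                    "dataset": ds, "tissue": tissue, "treatment": f"t{tau:g}",
                    "n_candidates": summ.n_candidates,
                    "n_shared": summ.n_shared,
                    "pct_tissue": summ.pct_tissue_rounded,
                })
    shared = pd.DataFrame(rows)
    _write(shared, outdir / "shared_summary.tsv")
    log["stages"]["screening"] = {"rows": len(shared)}
    logger.info("abundance-only mode: count-dependent stages skipped")
    report = ["# Screening report (abundance-only mode)", "",
              "Shared contaminant burden per data set, tissue and threshold:", "",
              shared.to_markdown(index=False), "",
              "Count-dependent stages (prevalence, removal, diversity, "
              "comparison) were skipped: inputs are relative abundances only.", ""]
    (outdir / "report.md").write_text("\n".join(report))
    return {"shared": shared}


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the in-memory stage outputs."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(cfg)
    log: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "stages": {},
    }

    try:
        if cfg.abundance_blocks is not None:
            out = _abundance_only_run(cfg, outdir, log)
            (outdir / "runlog.json").write_text(json.dumps(log, indent=2, default=str))
            return out

        if cfg.simulate is not None:
            gen = GeneratorConfig(**{**cfg.simulate, "seed": cfg.seed})
            table, metadata, truth = generate(gen)
            truth_df = pd.DataFrame({
                "label": pd.Series(truth.labels),
                "pooled_control_pct": (truth.pooled_control_abundance * 100.0)
                .reindex(truth.labels.keys()),
            })
            truth_df.index.name = "feature_id"
            _write(truth_df, outdir / "truth.tsv", index=True)
            table.to_tsv(outdir / "table_input.tsv")
            metadata.to_tsv(outdir / "metadata.tsv")
        else:
            table = read_feature_table(cfg.feature_table)
            metadata = SampleMetadata.from_tsv(cfg.metadata)
        metadata.validate_against(table)
        log["stages"]["input"] = {"shape": list(table.shape)}

        if cfg.filter_singletons:
            table = filter_singletons(table)
            log["stages"]["singletons"] = {"shape": list(table.shape)}
        if cfg.normalize:
            table = subsample_to_depth(table, NormalizationConfig(
                depth=cfg.depth, seed=cfg.seed, drop_below_depth=cfg.drop_below_depth))
            log["stages"]["normalize"] = {"depth": cfg.depth, "shape": list(table.shape)}

        contaminants, shared = screening_report(table, metadata, cfg.taus)
        _write(contaminants, outdir / "contaminants.tsv")
        _write(shared, outdir / "shared_summary.tsv")
        log["stages"]["screening"] = {"candidates": len(contaminants)}

        prev_rows = []
        for ds in metadata.datasets:
            ids = [s for s in table.sample_ids
                   if metadata.df.loc[s, "dataset"] == ds]
            sub = table.select_samples(ids)
            res = prevalence_results(sub, metadata)
            tab = prevalence_table(res, cfg.p_stars).reset_index()
            tab.insert(0, "dataset", ds)
            prev_rows.append(tab)
        prevalence = pd.concat(prev_rows, ignore_index=True)
        _write(prevalence, outdir / "prevalence.tsv")
        log["stages"]["prevalence"] = {"rows": len(prevalence)}

        specs = [TreatmentSpec.from_label(lbl) for lbl in cfg.treatments]
        comparisons = []
        letters_rows = []
        for ds in metadata.datasets:
            ids = [s for s in table.sample_ids if metadata.df.loc[s, "dataset"] == ds]
            sub = table.select_samples(ids)
            alpha_values: dict[str, dict[str, pd.Series]] = {m: {} for m in ALPHA_METRICS}
            beta_values: dict[str, dict[str, pd.Series]] = {m: {} for m in METRICS}
            for spec in specs:
                outcome = apply_treatment(sub, metadata, spec, ds)
                outcome.table_out.to_tsv(outdir / f"table_{ds}_{spec.label}.tsv")
                adf = alpha_diversity(outcome.table_out)
                _write(adf, outdir / f"alpha_{ds}_{spec.label}.tsv", index=True)
                for m in ALPHA_METRICS:
                    alpha_values[m][spec.label] = adf[m]
                for metric in METRICS:
                    dm = distance_matrix(outcome.table_out, metric)
                    _write(dm.to_frame(), outdir / f"beta_{metric}_{ds}_{spec.label}.tsv",
                           index=True)
                    beta_values[metric][spec.label] = dm.condensed()
                log["stages"][f"removal:{ds}:{spec.label}"] = {
                    "removed_features": len(outcome.removed_features),
                    "shape": list(outcome.table_out.shape),
                }
            for metric, values in {**alpha_values, **beta_values}.items():
                results, letters = compare_treatments(values, alpha=cfg.alpha,
                                                      order=cfg.treatments)
                comparisons.append(comparison_table(results, metric=metric, dataset=ds))
                for t, lset in letters.letters.items():
                    letters_rows.append({"dataset": ds, "metric": metric,
                                         "treatment": t, "letters": lset})
        comparisons_df = pd.concat(comparisons, ignore_index=True)
        letters_df = pd.DataFrame(letters_rows)
        _write(comparisons_df, outdir / "comparisons.tsv")
        _write(letters_df, outdir / "letters.tsv")
        log["stages"]["comparison"] = {"rows": len(comparisons_df)}

        _write_report(outdir, contaminants, shared, prevalence, comparisons_df,
                      letters_df)
        (outdir / "runlog.json").write_text(json.dumps(log, indent=2, default=str))
        return {
            "table": table, "metadata": metadata,
            "contaminants": contaminants, "shared": shared,
            "prevalence": prevalence, "comparisons": comparisons_df,
            "letters": letters_df,
        }
    except Exception as exc:
        stage = next(reversed(log["stages"]), "input") if log["stages"] else "input"
        raise type(exc)(f"[stage after {stage!r}] {exc}") from exc


def _write_report(outdir: Path, contaminants, shared, prevalence, comparisons,
                  letters) -> None:
    prev_counts = (
        prevalence.groupby("dataset")[[c for c in prevalence.columns
                                       if c.startswith("contaminant_")]]
        .sum().astype(int).reset_index()
    )
    sig = comparisons[comparisons["band"] != ""]
    lines = [
        "# Contamination screening report", "",
        "## Candidate contaminants (control abundance >= min tau)", "",
        contaminants.to_markdown(index=False), "",
        "## Shared contaminant burden", "",
        shared.to_markdown(index=False), "",
        "## Prevalence-test candidates per classification threshold", "",
        prev_counts.to_markdown(index=False), "",
        "## Diversity impact: significant treatment contrasts", "",
        sig.to_markdown(index=False) if len(sig) else "(none)", "",
        "## Letter displays", "",
        letters.to_markdown(index=False), "",
    ]
    (outdir / "report.md").write_text("\n".join(lines))
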