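"""End-to-end orchestration: simulate or ingest, normalize, optionally
infer+roll up, test differential abundance, PCA + supergroup assignment,
degradome analytics, marker diagnostics and overrepresentation testing.

A run is driven by one :class:`PipelineConfig` and a single seed; every
stage draws a deterministic substream, so re-running an identical config
reproduces byte-identical tables. Each run directory carries a manifest
with the config hash, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .degradome import (
    collect_flank_windows, detect_ladders, group_uniqueness, ladder_table,
)
from .diagnostics import (
    AMYLASE_CUTOFF_IU_L, AMYLASE_RICH_GROUPS, CEA_CUTOFF_NG_ML, MUCINOUS_GROUPS,
    marker_report,
)
from .enrichment import binomial_enrichment
from .normalize import log_transform, normalize_loess
from .pca import assign_supergroup, pca_fit, pca_project
from .rollup import infer_proteins, metaprotein_table, rollup_proteins
from .simulate import (
    DEFAULT_SUPERGROUPS, SimulationDesign, simulate_dataset, stage_rng,
)
from .stats import diff_test, select_significant
from .degradome import build_logo

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults mirror the analysis's printed
    thresholds (alpha 0.05, FC 1.5, CEA 192 ng/mL, amylase 250 IU/L)."""

    mode: str = "degradome"              # "degradome" (peptide level) | "proteome"
    seed: int = 0

    # inputs; when fasta/peptides/quant are None a synthetic study is generated
    fasta: str | None = None
    peptides: str | None = None
    quant: str | None = None
    samples: str | None = None
    annotations: str | None = None
    design: dict = field(default_factory=dict)   # SimulationDesign overrides

    # normalization
    span: float = 0.3
    anchor_fraction: float = 0.25
    min_present: int | None = None

    # differential testing
    alpha: float = 0.05
    fc_min: float = 1.5
    n_perm: int = 9999
    min_per_group: int = 2
    exhaustive_limit: int = 20000

    # multivariate: degradome matrices are sparse, so the default is
    # mean-imputation over features detected in >= 80% of samples
    pca_policy: str = "mean_impute"
    pca_min_present_frac: float = 0.8
    supergroups: tuple[tuple[str, ...], tuple[str, ...]] = DEFAULT_SUPERGROUPS
    unclassified_label: str = "UNC"

    # degradomics
    flank_width: int = 4
    min_rungs: int = 3

    # diagnostics
    cea_cutoff: float = CEA_CUTOFF_NG_ML
    amylase_cutoff: float = AMYLASE_CUTOFF_IU_L
    mucinous_groups: tuple[str, ...] = MUCINOUS_GROUPS
    amylase_rich_groups: tuple[str, ...] = AMYLASE_RICH_GROUPS

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_min < 1.0:
            raise ValueError("fc_min must be >= 1")
        if self.mode not in ("degradome", "proteome"):
            raise ValueError("mode must be 'degradome' or 'proteome'")
        if self.mode == "proteome" and self.quant is not None and self.peptides is None:
            raise ValueError("proteome mode on supplied quant requires a peptide table")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = cio.load_config(path) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "supergroups" in raw:
            raw["supergroups"] = tuple(tuple(g) for g in raw["supergroups"])
        for key in ("mucinous_groups", "amylase_rich_groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["supergroups"] = [list(g) for g in self.supergroups]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def _synthetic_annotations(db_accessions: list[str], seed: int) -> dict[str, set[str]]:
    """Random protein -> term table so the overrepresentation stage can run
    on fully synthetic studies (synthetic stand-in for a GO-Slim export)."""
    rng = stage_rng(seed, "annotations")
    terms = [f"TERM{i:02d}" for i in range(8)]
    ann: dict[str, set[str]] = {}
    for acc in db_accessions:
        k = 1 + int(rng.integers(0, 3))
        ann[acc] = set(rng.choice(terms, size=k, replace=False))
    return ann


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ inputs
    if config.quant is None:
        design = SimulationDesign(**{"seed": config.seed, **config.design})
        ds = simulate_dataset(design)
        db, peptides, quant, samples = ds.proteome, ds.peptides, ds.quant, ds.samples
        cio.write_fasta(db, out / "proteins.fasta")
        cio.write_peptide_table(peptides, out / "peptides.tsv")
        cio.write_quant_table(quant, out / "quant.tsv")
        cio.write_sample_table(samples, out / "samples.tsv")
        truth = {
            "true_diff_feature_ids": sorted(ds.truth.true_diff_feature_ids),
            "sample_supergroup": ds.truth.sample_supergroup,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        annotations = _synthetic_annotations(db.accessions, config.seed)
    else:
        db = cio.read_fasta(config.fasta) if config.fasta else None
        peptides = cio.read_peptide_table(config.peptides) if config.peptides else []
        quant = cio.read_quant_table(config.quant, scale="linear")
        samples = cio.read_sample_table(config.samples, allowed_groups=None)
        annotations = (
            cio.read_annotation_table(config.annotations) if config.annotations else None
        )
    cio.check_samples_match(quant, samples)
    pep_to_protein = {
        p.peptide_id: p.matches[0][0] for p in peptides if p.matches
    }

    # --------------------------------------------------------------- normalize
    logged = log_transform(quant)
    normalized, norm_model = normalize_loess(
        logged, fraction=config.anchor_fraction, span=config.span,
        min_present=config.min_present,
    )
    cio.write_quant_table(normalized, out / "normalized_quant.tsv")
    curves = pd.DataFrame(
        [
            (s, float(x), float(y))
            for s, (xs, ys) in norm_model.curves.items()
            for x, y in zip(xs, ys)
        ],
        columns=["sample_id", "abundance", "correction"],
    )
    cio.write_table(curves, out / "normalization_curves.tsv")

    # ------------------------------------------------- inference and roll-up
    if config.mode == "proteome":
        metas, pep_map = infer_proteins(peptides)
        cio.write_table(metaprotein_table(metas), out / "metaproteins.tsv")
        pep_map = {p: m for p, m in pep_map.items() if p in normalized.feature_ids}
        analysis_matrix = rollup_proteins(normalized, pep_map)
        cio.write_quant_table(analysis_matrix, out / "protein_quant.tsv")
        feature_to_protein = None
    else:
        analysis_matrix = normalized
        feature_to_protein = pep_to_protein or None

    groups = samples["group"]

    # ------------------------------------------------------------ differential
    diff = diff_test(
        analysis_matrix, groups, alpha=config.alpha, fc_min=config.fc_min,
        n_perm=config.n_perm, seed=config.seed,
        exhaustive_limit=config.exhaustive_limit,
        min_per_group=config.min_per_group,
        exclude_groups=(config.unclassified_label,),
    )
    cio.write_table(diff, out / "diff_results.tsv")
    significant = select_significant(diff[diff["tested"]], config.alpha, config.fc_min)
    cio.write_table(significant, out / "significant_features.tsv")

    # ------------------------------------------------------------ multivariate
    labeled_ids = [s for s in analysis_matrix.sample_ids
                   if groups.get(s) != config.unclassified_label]
    unc_ids = [s for s in analysis_matrix.sample_ids
               if groups.get(s) == config.unclassified_label]
    pca_data = analysis_matrix.data
    if unc_ids and config.pca_policy == "complete":
        # the unclassified samples must be projectable onto the model, so
        # completeness is required across all samples, not just labeled ones
        pca_data = pca_data.dropna(axis=0)
    labeled_qm = cio.QuantMatrix(pca_data[labeled_ids], "log2")
    model = pca_fit(labeled_qm, complete_policy=config.pca_policy,
                    min_present_frac=config.pca_min_present_frac)
    scores = model.scores.copy()
    scores.index.name = "sample_id"
    cio.write_table(scores, out / "scores.tsv", index=True)
    loadings = model.loadings.copy()
    loadings.index.name = "feature_id"
    cio.write_table(loadings, out / "loadings.tsv", index=True)
    cio.write_table(
        pd.DataFrame(
            {
                "component": model.scores.columns,
                "variance_fraction": model.variance_explained,
            }
        ),
        out / "variance.tsv",
    )
    if unc_ids:
        unc_qm = cio.QuantMatrix(pca_data[unc_ids], "log2")
        unc_scores = pca_project(model, unc_qm)
        assignments = assign_supergroup(model, groups, config.supergroups, unc_scores)
        assignments.index.name = "sample_id"
        cio.write_table(assignments, out / "assignments.tsv", index=True)

    # ------------------------------------------------------------- degradomics
    if peptides and db is not None:
        present = normalized.data.notna()
        group_logos = []
        for g in sorted(set(groups) - {config.unclassified_label}):
            cols = [s for s in normalized.sample_ids if groups.get(s) == g]
            det = set(present.index[present[cols].any(axis=1)])
            recs = [p for p in peptides if p.peptide_id in det and p.matches]
            if not recs:
                continue
            n_win, c_win = collect_flank_windows(recs, db, width=config.flank_width)
            for terminus, windows in (("N", n_win), ("C", c_win)):
                if not windows:
                    continue
                logo = build_logo(windows)
                freqs = logo.freqs.copy()
                freqs.insert(0, "position", freqs.index)
                freqs.insert(0, "terminus", terminus)
                freqs.insert(0, "group", g)
                freqs["info_bits"] = logo.info_bits
                group_logos.append(freqs)
        if group_logos:
            cio.write_table(pd.concat(group_logos, ignore_index=True),
                            out / "logos.tsv")

        ladders = detect_ladders(peptides, min_rungs=config.min_rungs)
        cio.write_table(ladder_table(ladders), out / "ladders.tsv")

    uniq = group_uniqueness(
        analysis_matrix, samples,
        feature_to_protein=feature_to_protein,
        exclude_groups=(config.unclassified_label,),
    )
    cio.write_table(uniq.table(), out / "uniqueness.tsv")

    # ------------------------------------------------------------- diagnostics
    diag_rows = []
    if "cea_ng_ml" in samples.columns:
        rep = marker_report(samples, "cea_ng_ml", config.mucinous_groups,
                            config.cea_cutoff, (config.unclassified_label,))
        diag_rows.append({"marker": "cea_ng_ml", **rep.__dict__})
    if "amylase_iu_l" in samples.columns:
        rep = marker_report(samples, "amylase_iu_l", config.amylase_rich_groups,
                            config.amylase_cutoff, (config.unclassified_label,))
        diag_rows.append({"marker": "amylase_iu_l", **rep.__dict__})
    if diag_rows:
        cio.write_table(pd.DataFrame(diag_rows), out / "diagnostics.tsv")

    # -------------------------------------------------------------- enrichment
    if annotations is not None and feature_to_protein is not None:
        background = sorted(
            {feature_to_protein[f] for f in analysis_matrix.feature_ids
             if f in feature_to_protein}
        )
        query = sorted(
            {feature_to_protein[f] for f in significant["feature_id"]
             if f in feature_to_protein}
        )
        if query:
            enr = binomial_enrichment(query, background, annotations, config.alpha)
            cio.write_table(enr, out / "enrichment.tsv")

    # ---------------------------------------------------------------- manifest
    manifest = {
        "package": "cystomics",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": config.to_dict(),
        "n_features": len(analysis_matrix.feature_ids),
        "n_samples": len(analysis_matrix.sample_ids),
        "n_significant": int(len(significant)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
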