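"""Downstream analyses and end-to-end orchestration.

Covers the Europe/non-Europe presence partition of segregating variants,
counts of newly predicted PGx variants by CPIC drug-count category,
per-population allele-frequency distributions by variant class, and a
single-config pipeline runner that chains simulate (or ingest) -> enrich ->
features -> train -> evaluate -> predict -> report.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import balance, enrichment, features, model, simulate
from .populations import DEFAULT_PANELS, EUROPEAN_LABELS, PANEL_LABELS


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class VennPartition:
    eur_only: int
    non_eur_only: int
    shared: int

    @property
    def total(self) -> int:
        return self.eur_only + self.non_eur_only + self.shared

    @property
    def fraction_carried_by_non_europeans(self) -> float:
        if self.total == 0:
            return float("nan")
        return (self.shared + self.non_eur_only) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eur_only": [self.eur_only],
                "non_eur_only": [self.non_eur_only],
                "shared": [self.shared],
                "total": [self.total],
                "fraction_carried_by_non_europeans": [
                    self.fraction_carried_by_non_europeans
                ],
            }
        )


@dataclass
class CategoryCounts:
    """Per-gene newly-predicted counts grouped by CPIC drug-count bin."""

    per_gene: pd.DataFrame  # gene_id, cpic_drug_count, bin, n_predicted
    bins: list[tuple[int, int]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for lo, hi in self.bins:
            label = _bin_label(lo, hi)
            counts = self.per_gene.loc[self.per_gene["bin"] == label, "n_predicted"]
            rows.append(
                {
                    "bin": label,
                    "n_genes": int(len(counts)),
                    "min": float(counts.min()) if len(counts) else float("nan"),
                    "q1": float(np.quantile(counts, 0.25)) if len(counts) else float("nan"),
                    "median": float(np.quantile(counts, 0.5)) if len(counts) else float("nan"),
                    "q3": float(np.quantile(counts, 0.75)) if len(counts) else float("nan"),
                    "max": float(counts.max()) if len(counts) else float("nan"),
                    "total_predicted": int(counts.sum()) if len(counts) else 0,
                }
            )
        return pd.DataFrame(rows)


def _bin_label(lo: int, hi: int) -> str:
    return str(lo) if lo == hi else f"{lo}-{hi}"


def _af_matrix(pop_af_table: pd.DataFrame) -> pd.DataFrame:
    """Validate and return the AF columns indexed by variant_id."""
    table = pop_af_table
    if "variant_id" in table.columns:
        table = table.set_index("variant_id")
    extra = [c for c in table.columns if c not in PANEL_LABELS]
    if extra:
        raise ValueError(f"unknown population labels in AF table: {extra}")
    missing = [c for c in PANEL_LABELS if c not in table.columns]
    if missing:
        raise ValueError(f"AF table missing population columns: {missing}")
    return table[list(PANEL_LABELS)]


def venn_partition(
    pop_af_table: pd.DataFrame,
    panels=DEFAULT_PANELS,
    presence_rule: str = "positive",
) -> VennPartition:
    """Partition segregating variants by European / non-European presence.

    A variant is present in a group iff its AF clears the presence rule in
    at least one panel of the group: ``"positive"`` means AF > 0,
    ``"frequency_floor"`` means AF >= 1/(2 * panel sample size). Variants
    absent everywhere are excluded.
    """
    afs = _af_matrix(pop_af_table)
    eur_labels = {p.label for p in panels if p.super_group == "EUR"}
    if presence_rule == "positive":
        present = afs.to_numpy() > 0
    elif presence_rule == "frequency_floor":
        floors = np.asarray(
            [1.0 / (2 * p.sample_size) for lbl in afs.columns for p in panels if p.label == lbl]
        )
        present = afs.to_numpy() >= floors[None, :]
    else:
        raise ValueError(f"unknown presence rule {presence_rule!r}")

    is_eur = np.asarray([c in eur_labels for c in afs.columns])
    in_eur = present[:, is_eur].any(axis=1)
    in_non = present[:, ~is_eur].any(axis=1)
    return VennPartition(
        eur_only=int((in_eur & ~in_non).sum()),
        non_eur_only=int((~in_eur & in_non).sum()),
        shared=int((in_eur & in_non).sum()),
    )


def _default_bins(counts: Iterable[int]) -> list[tuple[int, int]]:
    return [(c, c) for c in sorted(set(int(c) for c in counts))]


def counts_by_category(
    gene_table: pd.DataFrame,
    variant_genes: pd.Series,
    predicted_ids: Iterable[str],
    bins: Sequence[tuple[int, int]] | None = None,
) -> CategoryCounts:
    """Group per-pharmacogene newly-predicted variant counts by CPIC
    drug-count bin.

    ``variant_genes`` maps variant_id -> gene_id; ``bins`` are inclusive
    (lo, hi) ranges that must not overlap and must cover every observed
    drug count; default is one unit bin per observed count.
    """
    pgx = gene_table.loc[gene_table["is_pharmacogene"].astype(bool)].copy()
    if bins is None:
        bin_list = _default_bins(pgx["cpic_drug_count"])
    else:
        bin_list = [(int(lo), int(hi)) for lo, hi in bins]
        for lo, hi in bin_list:
            if lo > hi:
                raise ValueError(f"bin ({lo}, {hi}) has lo > hi")
        ordered = sorted(bin_list)
        for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
            if hi1 >= lo2:
                raise ValueError(f"bins ({lo1},{hi1}) and ({lo2},{hi2}) overlap")

    def assign(count: int) -> str:
        for lo, hi in bin_list:
            if lo <= count <= hi:
                return _bin_label(lo, hi)
        raise ValueError(f"drug count {count} falls in no bin")

    predicted = pd.Index(set(predicted_ids))
    pred_genes = variant_genes.loc[variant_genes.index.intersection(predicted)]
    per_gene_pred = pred_genes.value_counts()

    pgx["bin"] = [assign(int(c)) for c in pgx["cpic_drug_count"]]
    pgx["n_predicted"] = (
        pgx["gene_id"].map(per_gene_pred).fillna(0).astype(int)
    )
    per_gene = pgx[["gene_id", "cpic_drug_count", "bin", "n_predicted"]].reset_index(
        drop=True
    )
    return CategoryCounts(per_gene=per_gene, bins=bin_list)


def af_by_class_population(
    pop_af_table: pd.DataFrame, class_assignment: pd.Series
) -> pd.DataFrame:
    """Five-number AF summary per (population, variant class), long format.

    ``class_assignment`` maps variant_id -> class name; every variant in the
    AF table must be assigned exactly one class.
    """
    afs = _af_matrix(pop_af_table)
    cls = class_assignment.reindex(afs.index)
    if cls.isna().any():
        missing = list(afs.index[cls.isna()])[:5]
        raise ValueError(f"variants without class assignment, e.g. {missing}")
    rows = []
    for pop in afs.columns:
        for name, group in afs.groupby(cls, sort=True):
            v = group[pop].to_numpy(dtype=float)
            rows.append(
                {
                    "population": pop,
                    "class": name,
                    "min": float(v.min()),
                    "q1": float(np.quantile(v, 0.25)),
                    "median": float(np.quantile(v, 0.5)),
                    "q3": float(np.quantile(v, 0.75)),
                    "max": float(v.max()),
                    "n": int(len(v)),
                }
            )
    return pd.DataFrame(rows)


def plot_af_boxplots(af_summary: pd.DataFrame, path: str) -> None:
    """Optional convenience: one panel per class, boxes from the stored
    quartiles. Tables are the contract; this is a side-effect-free extra."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted(af_summary["class"].unique())
    fig, axes = plt.subplots(len(classes), 1, figsize=(12, 3 * len(classes)), squeeze=False)
    for ax, cls in zip(axes[:, 0], classes):
        sub = af_summary[af_summary["class"] == cls]
        pops = list(sub["population"])
        stats = [
            {
                "label": r.population,
                "whislo": r.min,
                "q1": r.q1,
                "med": r.median,
                "q3": r.q3,
                "whishi": r.max,
            }
            for r in sub.itertuples()
        ]
        ax.bxp(stats, showfliers=False)
        ax.set_title(cls)
        ax.set_xticklabels(pops, rotation=90)
        ax.set_ylabel("non-reference AF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_SIGNATURE_SIZES = {"iHS": 9593, "XP-CLR": 8636, "D": 17734}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""

    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Guard()


def run_pipeline(config: Mapping, out_dir: str | None = None) -> dict:
    """Execute the full analysis from a single config mapping.

    Writes all output tables plus a ``manifest.json`` with seeds, version,
    and input hashes into ``out_dir``. Deterministic and idempotent for a
    fixed config. Returns a dict of written paths.
    """
    config = dict(config)
    out_dir = out_dir or config.get("out_dir")
    if not out_dir:
        raise PipelineError("stage 'setup' failed: no output directory configured")
    os.makedirs(out_dir, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    ss = np.random.SeedSequence(master_seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ("genes", "variants", "signatures", "enrich", "partition", "train"),
            ss.spawn(6),
        )
    }
    paths: dict[str, str] = {}

    def _write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = os.path.join(out_dir, name)
        frame.to_csv(path, sep="\t", index=index)
        paths[name] = path

    # -- simulate or ingest ------------------------------------------------
    sim_cfg = dict(config.get("simulate", {}))
    input_cfg = dict(config.get("input", {}))
    if input_cfg:
        with _stage("ingest"):
            for key in ("variant_table", "gene_table"):
                if key not in input_cfg:
                    raise FileNotFoundError(f"input path {key!r} not configured")
                if not os.path.exists(input_cfg[key]):
                    raise FileNotFoundError(f"{key} not found: {input_cfg[key]}")
            variants, afs = simulate.read_variant_table(input_cfg["variant_table"])
            gene_frame = pd.read_csv(input_cfg["gene_table"], sep="\t")
            genes = simulate.frame_to_genes(gene_frame)
    else:
        with _stage("simulate"):
            sim_cfg.setdefault("seed", seeds["variants"])
            scfg = simulate.SimulationConfig.from_dict(sim_cfg)
            genes = simulate.generate_genes(
                scfg.n_genes, scfg.pgx_fraction, seed=seeds["genes"]
            )
            variants, afs = simulate.generate_variant_table(
                genes, scfg.n_variants, scfg
            )
            gene_frame = simulate.genes_to_frame(genes)
    _write("genes.tsv", gene_frame)
    simulate.write_variant_table(variants, afs, os.path.join(out_dir, "variants.tsv"))
    paths["variants.tsv"] = os.path.join(out_dir, "variants.tsv")

    pharmacogenes = {g.gene_id for g in genes if g.is_pharmacogene}

    # -- enrichment --------------------------------------------------------
    with _stage("enrich"):
        sig_cfg = dict(config.get("signatures", {}))
        sizes = dict(sig_cfg.get("sizes", {}))
        if not sizes:
            n_genes = len(genes)
            sizes = {
                stat: min(size, max(1, n_genes // 3))
                for stat, size in DEFAULT_SIGNATURE_SIZES.items()
            }
        signatures = simulate.generate_adaptive_signatures(
            genes,
            sizes,
            enrichment_factor=float(sig_cfg.get("enrichment_factor", 2.0)),
            seed=seeds["signatures"],
        )
        enrich_cfg = dict(config.get("enrich", {}))
        results = enrichment.enrich_signatures(
            universe_size=len(genes),
            pharmacogene_set=pharmacogenes,
            signatures=signatures,
            n_permutations=int(enrich_cfg.get("n_permutations", 1000)),
            seed=seeds["enrich"],
        )
        _write("enrichment.tsv", enrichment.results_to_frame(results))

    # -- features ----------------------------------------------------------
    with _stage("features"):
        matrix = variants.set_index("variant_id")[list(features.PREDICTORS)]
        labels = variants.set_index("variant_id")["label"].astype(bool)

    # -- train -------------------------------------------------------------
    train_cfg = dict(config.get("train", {}))
    smote_cfg = balance.SmoteConfig(**dict(config.get("smote", {})))
    learner = train_cfg.get("learner", "gradient_boosted_trees")
    threshold = float(train_cfg.get("threshold", 0.5))
    with _stage("train"):
        train_idx, test_idx = model.stratified_partition(
            labels.to_numpy(),
            train_fraction=float(train_cfg.get("train_fraction", 0.70)),
            seed=seeds["partition"],
        )
        grid = model.FAST_GRIDS[learner] if train_cfg.get("fast", True) else None
        cv_result, fitted = model.repeated_cv_train(
            learner,
            matrix.iloc[train_idx],
            labels.iloc[train_idx].to_numpy(),
            folds=int(train_cfg.get("folds", 5)),
            repeats=int(train_cfg.get("repeats", 10)),
            selection_metric=train_cfg.get("selection_metric", "sensitivity"),
            smote_config=smote_cfg,
            seed=seeds["train"],
            param_grid=grid,
            threshold=threshold,
        )
        _write("resamples.tsv", cv_result.resample_metrics, index=True)
        _write("cv_summary.tsv", cv_result.summary, index=True)

    # -- evaluate ----------------------------------------------------------
    with _stage("evaluate"):
        cm = model.evaluate_test(
            fitted, matrix.iloc[test_idx], labels.iloc[test_idx], threshold=threshold
        )
        _write("confusion.tsv", cm.to_table(), index=True)
        imp = model.variable_importance(fitted, list(matrix.columns))
        _write("importance.tsv", imp.table)

    # -- predict -----------------------------------------------------------
    with _stage("predict"):
        annotated_ids = set(labels.index[labels])
        score_frame = model.predict_scores(fitted, matrix)
        _write("predictions.tsv", score_frame)
        predicted_new = model.predict_new(
            fitted, matrix, annotated_ids, threshold=threshold
        )

    # -- report ------------------------------------------------------------
    with _stage("report"):
        afs_indexed = afs.set_index("variant_id")
        venn = venn_partition(afs_indexed)
        _write("venn.tsv", venn.to_frame())

        variant_genes = variants.set_index("variant_id")["gene_id"]
        cats = counts_by_category(gene_frame, variant_genes, predicted_new)
        _write("category_counts.tsv", cats.summary())

        cls = pd.Series("neutral", index=afs_indexed.index, name="class")
        cls[cls.index.isin(annotated_ids)] = "annotated"
        cls[cls.index.isin(predicted_new)] = "predicted"
        af_summary = af_by_class_population(afs_indexed, cls)
        _write("af_by_class.tsv", af_summary)

    manifest = {
        "seed": master_seed,
        "stage_seeds": seeds,
        "config": {k: v for k, v in config.items() if k != "out_dir"},
        "package_version": _package_version(),
        "n_genes": int(len(genes)),
        "n_variants": int(len(variants)),
        "n_predicted_new": int(len(predicted_new)),
        "chosen_hyperparameters": cv_result.chosen_hyperparameters,
        "input_hashes": {
            name: _sha256(path) for name, path in sorted(paths.items())
        },
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    paths["manifest.json"] = manifest_path
    return paths


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("pgxpipe")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"
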