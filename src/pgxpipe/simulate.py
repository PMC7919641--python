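"""Synthetic gene universes, variant feature tables, population allele
frequencies, and adaptive-signature gene sets.

The generator encodes the qualitative structure the downstream analysis
assumes: functional variant classes (already-annotated and to-be-predicted)
are common and enriched for candidate adaptive polymorphisms, putatively
neutral variants are rare, and per-population allele frequencies diverge
from the global frequency under a Balding–Nichols model with a single FST
parameter. All magnitudes are artifact defaults, exposed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .features import EVO_RATE_MAX, EVO_TIME_MAX, FLAG_NAMES, PREDICTORS
from .populations import AFRICAN_LABELS, DEFAULT_PANELS, PANEL_LABELS

#: Variant classes, in the order class fractions are specified.
VARIANT_CLASSES: tuple[str, ...] = ("annotated", "predicted", "neutral")

#: Default CPIC drug-count categories and their sampling weights among
#: pharmacogenes (0 = PharmGKB-annotated but no curated gene-drug pair).
DEFAULT_DRUG_COUNT_WEIGHTS: dict[int, float] = {
    0: 0.55,
    1: 0.18,
    2: 0.09,
    3: 0.05,
    4: 0.04,
    5: 0.03,
    6: 0.02,
    7: 0.015,
    12: 0.01,
    21: 0.005,
    22: 0.004,
    36: 0.003,
    60: 0.003,
}


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    is_pharmacogene: bool
    cpic_drug_count: int = 0

    def __post_init__(self) -> None:
        if self.cpic_drug_count < 0:
            raise ValueError("cpic_drug_count must be non-negative")
        if not self.is_pharmacogene and self.cpic_drug_count != 0:
            raise ValueError("non-pharmacogenes must have cpic_drug_count == 0")


@dataclass
class ClassParams:
    """Per-class generating distributions for the 14 predictors."""

    maf_beta: tuple[float, float] = (2.0, 5.0)
    cap_probability: float = 0.4
    ep_ref_beta: tuple[float, float] = (2.0, 4.0)
    ep_alt_beta: tuple[float, float] = (3.0, 3.0)
    evo_rate_beta: tuple[float, float] = (1.5, 6.0)
    evo_time_beta: tuple[float, float] = (3.0, 3.0)
    flag_rates: dict[str, float] = field(
        default_factory=lambda: {
            "topo_domain": 0.30,
            "chain": 0.60,
            "domain": 0.25,
            "helix": 0.15,
            "repeat": 0.05,
            "proteome": 0.90,
            "disulfide": 0.05,
            "variants": 0.20,
        }
    )

    def validate(self) -> None:
        if not 0 <= self.cap_probability <= 1:
            raise ValueError("cap_probability must be in [0, 1]")
        for name in FLAG_NAMES:
            rate = self.flag_rates.get(name)
            if rate is None or not 0 <= rate <= 1:
                raise ValueError(f"flag rate for {name!r} missing or outside [0, 1]")


def _neutral_params() -> ClassParams:
    return ClassParams(
        maf_beta=(0.5, 20.0),
        cap_probability=0.05,
        ep_ref_beta=(4.0, 2.0),
        ep_alt_beta=(1.5, 5.0),
        evo_rate_beta=(1.5, 6.0),
        evo_time_beta=(2.0, 4.0),
        flag_rates={
            "topo_domain": 0.20,
            "chain": 0.55,
            "domain": 0.20,
            "helix": 0.12,
            "repeat": 0.04,
            "proteome": 0.88,
            "disulfide": 0.04,
            "variants": 0.15,
        },
    )


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_variants: int = 20000
    pgx_fraction: float = 0.10
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"annotated": 0.03, "predicted": 0.07, "neutral": 0.90}
    )
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: {
            "annotated": ClassParams(),
            "predicted": ClassParams(),
            "neutral": _neutral_params(),
        }
    )
    divergence_fst: float = 0.02
    african_shift: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        if not 0 <= self.pgx_fraction <= 1:
            raise ValueError("pgx_fraction must be in [0, 1]")
        if set(self.class_fractions) != set(VARIANT_CLASSES):
            raise ValueError(f"class_fractions must have keys {VARIANT_CLASSES}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if not 0 <= self.divergence_fst < 1:
            raise ValueError("divergence_fst must be in [0, 1)")
        if self.african_shift < 0:
            raise ValueError("african_shift must be >= 0")
        for cls in VARIANT_CLASSES:
            self.class_params[cls].validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "class_params" in data:
            params = {}
            for name, sub in data["class_params"].items():
                sub = dict(sub)
                for key in ("maf_beta", "ep_ref_beta", "ep_alt_beta", "evo_rate_beta", "evo_time_beta"):
                    if key in sub:
                        sub[key] = tuple(sub[key])
                params[name] = ClassParams(**sub)
            data["class_params"] = params
        config = cls(**data)
        config.validate()
        return config


def generate_genes(
    n_genes: int,
    pgx_fraction: float,
    drug_count_weights: Mapping[int, float] | None = None,
    seed: int = 0,
) -> list[GeneRecord]:
    """Draw a gene universe with a pharmacogene subset and CPIC drug counts.

    Exactly ``round(n_genes * pgx_fraction)`` genes are flagged as
    pharmacogenes; only those receive a (possibly zero) CPIC drug count,
    drawn from ``drug_count_weights``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not 0 <= pgx_fraction <= 1:
        raise ValueError("pgx_fraction must be in [0, 1]")
    weights = dict(drug_count_weights or DEFAULT_DRUG_COUNT_WEIGHTS)
    if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise ValueError("drug_count_weights must be non-negative and sum > 0")

    rng = np.random.default_rng(seed)
    n_pgx = round(n_genes * pgx_fraction)
    width = max(6, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    pgx_idx = set(rng.choice(n_genes, size=n_pgx, replace=False).tolist())

    counts = np.asarray(sorted(weights), dtype=np.int64)
    probs = np.asarray([weights[c] for c in sorted(weights)], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(counts, size=n_pgx, p=probs)

    genes: list[GeneRecord] = []
    k = 0
    for i, gid in enumerate(gene_ids):
        if i in pgx_idx:
            genes.append(GeneRecord(gid, True, int(drawn[k])))
            k += 1
        else:
            genes.append(GeneRecord(gid, False, 0))
    return genes


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Per-panel allele frequency around global frequency ``p`` at given FST.

    FST = 0 degenerates to the global frequency; p = 0 or 1 stay fixed.
    """
    if fst == 0:
        return p.copy()
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    scale = (1.0 - fst) / fst
    out[~interior] = p[~interior]
    pi = p[interior]
    out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def generate_variant_table(
    genes: Sequence[GeneRecord],
    n_variants: int,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the labeled variant feature table and the per-population AF table.

    Returns ``(variants, afs)``: ``variants`` has columns ``variant_id,
    gene_id, class, label`` plus the 14 predictors in canonical order;
    ``afs`` has ``variant_id`` plus one column per population code. Variants
    are assigned to pharmacogenes only (the analysis universe is
    pharmacogene missense variation); the wider gene universe exists for
    enrichment testing.
    """
    config.validate()
    if n_variants < 1:
        raise ValueError("n_variants must be positive")
    pgx_ids = [g.gene_id for g in genes if g.is_pharmacogene]
    if not pgx_ids:
        raise ValueError("gene universe contains no pharmacogene")

    rng = np.random.default_rng(config.seed)
    fractions = np.asarray([config.class_fractions[c] for c in VARIANT_CLASSES])
    cls_idx = rng.choice(len(VARIANT_CLASSES), size=n_variants, p=fractions)
    classes = np.asarray(VARIANT_CLASSES, dtype=object)[cls_idx]
    gene_assign = rng.choice(np.asarray(pgx_ids, dtype=object), size=n_variants)

    width = max(6, len(str(n_variants)))
    variant_ids = [f"var{i:0{width}d}" for i in range(1, n_variants + 1)]

    cols: dict[str, np.ndarray] = {p: np.zeros(n_variants) for p in PREDICTORS}
    for ci, cls in enumerate(VARIANT_CLASSES):
        mask = cls_idx == ci
        m = int(mask.sum())
        if m == 0:
            continue
        params = config.class_params[cls]
        cols["maf"][mask] = rng.beta(*params.maf_beta, size=m)
        cols["cap"][mask] = rng.random(m) < params.cap_probability
        cols["ep_ref"][mask] = rng.beta(*params.ep_ref_beta, size=m)
        cols["ep_alt"][mask] = rng.beta(*params.ep_alt_beta, size=m)
        cols["evo_rate"][mask] = EVO_RATE_MAX * rng.beta(*params.evo_rate_beta, size=m)
        cols["evo_time"][mask] = EVO_TIME_MAX * rng.beta(*params.evo_time_beta, size=m)
        for name in FLAG_NAMES:
            cols[name][mask] = rng.random(m) < params.flag_rates[name]

    variants = pd.DataFrame({"variant_id": variant_ids, "gene_id": gene_assign})
    variants["class"] = classes
    variants["label"] = classes == "annotated"
    for p in PREDICTORS:
        if p in ("cap",) + FLAG_NAMES:
            variants[p] = cols[p].astype(np.int64)
        else:
            variants[p] = cols[p]

    global_af = cols["maf"]
    predicted_mask = classes == "predicted"
    afs = pd.DataFrame({"variant_id": variant_ids})
    for panel in DEFAULT_PANELS:
        p = global_af.copy()
        if config.african_shift > 0 and panel.label in AFRICAN_LABELS:
            interior = predicted_mask & (p > 0) & (p < 1)
            p[interior] = expit(logit(p[interior]) + config.african_shift)
        afs[panel.label] = _balding_nichols(rng, p, config.divergence_fst)
    return variants, afs


def generate_adaptive_signatures(
    genes: Sequence[GeneRecord],
    sizes_by_statistic: Mapping[str, int],
    enrichment_factor: float = 1.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Draw one gene-id set per selection-scan statistic, without replacement.

    ``enrichment_factor`` multiplies the sampling weight of pharmacogenes;
    1.0 gives uniform draws (the enrichment test's null).
    """
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    n_genes = len(genes)
    ids = np.asarray([g.gene_id for g in genes], dtype=object)
    weights = np.asarray(
        [enrichment_factor if g.is_pharmacogene else 1.0 for g in genes]
    )
    if weights.sum() == 0:
        raise ValueError("all sampling weights are zero")
    # uniform weights take numpy's fast unweighted path
    uniform = bool(np.all(weights == weights[0]))
    probs = None if uniform else weights / weights.sum()

    rng = np.random.default_rng(seed)
    out: dict[str, set[str]] = {}
    for stat, size in sizes_by_statistic.items():
        if size > n_genes:
            raise ValueError(
                f"signature size {size} for {stat!r} exceeds universe size {n_genes}"
            )
        if size < 0:
            raise ValueError("signature sizes must be non-negative")
        if probs is not None and np.count_nonzero(probs) < size:
            raise ValueError(
                f"cannot draw {size} genes without replacement: only "
                f"{np.count_nonzero(probs)} have non-zero weight"
            )
        drawn = rng.choice(ids, size=size, replace=False, p=probs)
        out[stat] = set(drawn.tolist())
    return out


def genes_to_frame(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_pharmacogene": [int(g.is_pharmacogene) for g in genes],
            "cpic_drug_count": [g.cpic_drug_count for g in genes],
        }
    )


def frame_to_genes(frame: pd.DataFrame) -> list[GeneRecord]:
    return [
        GeneRecord(str(r.gene_id), bool(r.is_pharmacogene), int(r.cpic_drug_count))
        for r in frame.itertuples(index=False)
    ]


def write_variant_table(variants: pd.DataFrame, afs: pd.DataFrame, path) -> None:
    """Write the combined variant + AF table as TSV (one row per variant)."""
    merged = variants.merge(afs, on="variant_id", validate="one_to_one")
    merged.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_variant_table`."""
    merged = pd.read_csv(path, sep="\t")
    af_cols = [c for c in PANEL_LABELS if c in merged.columns]
    variants = merged.drop(columns=af_cols)
    afs = merged[["variant_id", *af_cols]].copy()
    return variants, afs


def write_signature_sets(signatures: Mapping[str, set[str]], out_dir) -> dict[str, str]:
    """One gene id per line, one file per statistic. Returns written paths."""
    import os

    paths = {}
    os.makedirs(out_dir, exist_ok=True)
    for stat, members in signatures.items():
        safe = stat.replace("/", "_")
        path = os.path.join(out_dir, f"signature_{safe}.txt")
        with open(path, "w") as fh:
            for gid in sorted(members):
                fh.write(f"{gid}\n")
        paths[stat] = path
    return paths


def read_id_set(path) -> set[str]:
    """Read a one-id-per-line text file into a set."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
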