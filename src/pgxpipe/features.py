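"""Assembly of the 14-variable model matrix for missense variants.

Predictors are: global minor allele frequency, candidate adaptive
polymorphism (CAP) membership, four per-position evolutionary statistics
(evolutionary time span, evolutionary rate, and the evolutionary probability
of the reference and of the non-reference allele), and eight binary protein
feature-track flags coded present/absent.

Coordinate conventions: variant positions are 1-based (VCF convention);
feature tracks are BED, 0-based half-open. A variant at 1-based position P
carries a flag iff P-1 falls inside some [start, end) interval of the track
on the same chromosome.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Binary protein feature tracks entering the model, in model-matrix order.
FLAG_NAMES: tuple[str, ...] = (
    "topo_domain",
    "chain",
    "domain",
    "helix",
    "repeat",
    "proteome",
    "disulfide",
    "variants",
)

#: The 14 predictor columns, in canonical model-matrix order.
PREDICTORS: tuple[str, ...] = (
    "maf",
    "cap",
    "evo_time",
    "ep_alt",
    "topo_domain",
    "evo_rate",
    "chain",
    "ep_ref",
    "domain",
    "helix",
    "repeat",
    "proteome",
    "disulfide",
    "variants",
)

#: Continuous (non-binary) predictors.
CONTINUOUS_PREDICTORS: tuple[str, ...] = (
    "maf",
    "ep_ref",
    "ep_alt",
    "evo_rate",
    "evo_time",
)

EVO_RATE_MAX = 57_405.0
EVO_TIME_MAX = 2_774.0


class BedParseError(ValueError):
    """A BED line could not be parsed."""


class DataIntegrityError(ValueError):
    """Input tables violate keying assumptions (e.g. duplicate variant ids)."""


@dataclass
class FeatureIntervals:
    """A named set of genomic intervals in 0-based half-open convention."""

    track_name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"track {self.track_name!r}: interval {chrom}:{start}-{end} "
                    "has start >= end"
                )
        self.intervals.sort()
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        # Merge overlapping intervals per chromosome so that membership can be
        # answered with one searchsorted over non-overlapping spans.
        for chrom, ivals in by_chrom.items():
            merged: list[list[int]] = []
            for start, end in sorted(ivals):
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            arr = np.asarray(merged, dtype=np.int64)
            self._index[chrom] = (arr[:, 0], arr[:, 1])

    def contains(self, chroms: Sequence[str], pos0: Sequence[int]) -> np.ndarray:
        """Vectorised membership test for 0-based positions."""
        chroms = np.asarray(chroms, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(len(pos0), dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in self._index:
                continue
            starts, ends = self._index[chrom]
            mask = chroms == chrom
            p = pos0[mask]
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = idx >= 0
            hit = np.zeros(len(p), dtype=bool)
            hit[ok] = p[ok] < ends[idx[ok]]
            out[mask] = hit
        return out


def read_bed(path: str | os.PathLike, track_name: str | None = None) -> FeatureIntervals:
    """Parse one 3+ column BED file into a :class:`FeatureIntervals`.

    Raises :class:`BedParseError` with the offending line number for
    non-integer coordinates or inverted intervals. Empty files yield an empty
    (valid) track.
    """
    name = track_name or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, "
                    f"{fields[2]!r}"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: inverted or empty interval {start} >= {end}"
                )
            intervals.append((chrom, start, end))
    return FeatureIntervals(name, intervals)


def read_bed_tracks(paths: Iterable[str | os.PathLike]) -> dict[str, FeatureIntervals]:
    """Read several BED files, keyed by filename stem."""
    tracks = {}
    for path in paths:
        track = read_bed(path)
        tracks[track.track_name] = track
    return tracks


def encode_uniprot(
    variants: pd.DataFrame, tracks: Mapping[str, FeatureIntervals]
) -> pd.DataFrame:
    """Code feature tracks as present (1) / absent (0) per variant.

    ``variants`` needs ``chrom`` and 1-based ``position`` columns; the result
    has one 0/1 column per track, indexed like ``variants``.
    """
    pos0 = variants["position"].to_numpy(dtype=np.int64) - 1
    chroms = variants["chrom"].to_numpy(dtype=object)
    out = {}
    for name, track in tracks.items():
        out[name] = track.contains(chroms, pos0).astype(np.int64)
    return pd.DataFrame(out, index=variants.index)


def label_from_annotations(
    variant_ids: Sequence[str], annotated_id_set: Iterable[str]
) -> pd.Series:
    """Boolean label per variant: annotated pharmacovariant or not."""
    annotated = frozenset(annotated_id_set)
    ids = pd.Index(variant_ids)
    return pd.Series([v in annotated for v in ids], index=ids, name="label")


def _validate_ranges(matrix: pd.DataFrame) -> None:
    for col in ("maf", "ep_ref", "ep_alt"):
        vals = matrix[col]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"column {col!r} has values outside [0, 1]")
    if ((matrix["evo_rate"] < 0) | (matrix["evo_rate"] > EVO_RATE_MAX)).any():
        raise ValueError(f"evo_rate outside [0, {EVO_RATE_MAX:g}]")
    if ((matrix["evo_time"] < 0) | (matrix["evo_time"] > EVO_TIME_MAX)).any():
        raise ValueError(f"evo_time outside [0, {EVO_TIME_MAX:g}]")


def assemble_features(
    variants: pd.DataFrame,
    flags: pd.DataFrame,
    evo_table: pd.DataFrame,
    cap_set: Iterable[str],
    maf_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-variant inputs into the 14-column model matrix.

    Parameters
    ----------
    variants
        One row per variant with at least a ``variant_id`` column; feature
        flags in ``flags`` must be index-aligned with it.
    evo_table
        ``variant_id, ep_ref, ep_alt, evo_rate, evo_time``. Variants missing
        from it, or with any statistic missing, are dropped (retention rule).
    cap_set
        Ids of candidate adaptive polymorphisms (binary feature).
    maf_table
        ``variant_id, maf``. Variants with missing MAF are dropped, not
        imputed.

    Returns
    -------
    (model_matrix, drop_log)
        ``model_matrix`` is indexed by variant_id with exactly the 14
        predictor columns in canonical order; ``drop_log`` records each
        excluded variant with its reason.
    """
    if variants["variant_id"].duplicated().any():
        dupes = variants.loc[variants["variant_id"].duplicated(), "variant_id"]
        raise DataIntegrityError(
            f"duplicate variant ids in variant table: {sorted(set(dupes))[:5]}"
        )
    for table, label in ((evo_table, "evolutionary"), (maf_table, "MAF")):
        if table["variant_id"].duplicated().any():
            raise DataIntegrityError(f"duplicate variant ids in {label} table")

    base = variants.set_index("variant_id")
    flags = flags.set_axis(base.index)
    evo = evo_table.set_index("variant_id")[["ep_ref", "ep_alt", "evo_rate", "evo_time"]]
    maf = maf_table.set_index("variant_id")["maf"]
    cap = frozenset(cap_set)

    merged = base.join(evo, how="left").join(maf, how="left")
    drops: list[tuple[str, str]] = []
    missing_evo = merged[["ep_ref", "ep_alt", "evo_rate", "evo_time"]].isna().any(axis=1)
    for vid in merged.index[missing_evo]:
        drops.append((vid, "no evolutionary probability"))
    missing_maf = merged["maf"].isna() & ~missing_evo
    for vid in merged.index[missing_maf]:
        drops.append((vid, "missing MAF"))

    kept = merged.index[~(missing_evo | merged["maf"].isna())]
    matrix = pd.DataFrame(index=kept)
    matrix["maf"] = merged.loc[kept, "maf"]
    matrix["cap"] = np.asarray([int(v in cap) for v in kept], dtype=np.int64)
    for col in ("ep_ref", "ep_alt", "evo_rate", "evo_time"):
        matrix[col] = merged.loc[kept, col].astype(float)
    for name in FLAG_NAMES:
        if name not in flags.columns:
            raise KeyError(f"feature flag track {name!r} missing from flags")
        matrix[name] = flags.loc[kept, name].astype(np.int64)
    matrix = matrix[list(PREDICTORS)]
    _validate_ranges(matrix)

    drop_log = pd.DataFrame(drops, columns=["variant_id", "reason"])
    return matrix, drop_log


def read_vcf_sites(path: str | os.PathLike) -> pd.DataFrame:
    """Sites-only parse of a VCF into (variant_id, chrom, position, ref, alt).

    Genotypes are ignored; multi-allelic records yield one row per ALT.
    Records without an ID get a ``chrom:pos:ref:alt`` id.
    """
    from pysam import VariantFile  # optional dependency, imported lazily

    rows = []
    with VariantFile(os.fspath(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                rows.append((vid, rec.chrom, rec.pos, rec.ref, alt))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "position", "ref", "alt"])
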