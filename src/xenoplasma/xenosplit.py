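"""Assign plasma reads to human or mouse origin on a combined reference.

Strategy: keep only uniquely mapped reads (alignment multiplicity NH = 1),
mask genomic regions where pure-species control samples empirically
cross-mapped to the other genome, then count reads per gene in union mode.
Alignment records are plain tables (one row per mapped read) so the stage is
testable without alignment binaries; an adapter for real name-sorted SAM/BAM
with NH tags can produce the same table.

All intervals are 0-based half-open (BED-compatible); strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "MaskSet",
    "select_unique",
    "derive_mask",
    "apply_mask",
    "count_by_gene",
    "count_species_totals",
    "merge_intervals",
]

ENDOGENOUS = ("human", "mouse")

ALIGNMENT_COLUMNS = (
    "sample_id", "read_id", "mapped_species", "contig", "start", "end",
    "n_hits", "true_species",
)


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge possibly overlapping/adjacent [start, end) intervals; idempotent."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    order = np.lexsort((iv[:, 1], iv[:, 0]))
    iv = iv[order]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:  # overlapping or book-ended: merge
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


@dataclass
class MaskSet:
    """Sorted, disjoint masked intervals per (species, contig)."""

    intervals: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.intervals = {
            key: merge_intervals(iv) for key, iv in self.intervals.items() if len(iv)
        }

    @property
    def n_intervals(self) -> int:
        return sum(len(iv) for iv in self.intervals.values())

    @property
    def total_bp(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values())
        )

    def is_empty(self) -> bool:
        return self.n_intervals == 0

    def overlaps(self, species: str, contig: str, start, end) -> np.ndarray:
        """Vectorized ≥1-bp overlap query against the mask on one contig."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        iv = self.intervals.get((species, contig))
        if iv is None or len(iv) == 0:
            return np.zeros(start.shape, dtype=bool)
        # first interval whose end is > start; overlap iff its start < end
        idx = np.searchsorted(iv[:, 1], start, side="right")
        hit = idx < len(iv)
        res = np.zeros(start.shape, dtype=bool)
        res[hit] = iv[idx[hit], 0] < end[hit]
        return res

    def to_bed(self, path) -> None:
        """Write as BED (contig, start, end, species)."""
        with open(path, "w") as fh:
            for (species, contig), iv in sorted(self.intervals.items()):
                for s, e in iv:
                    fh.write(f"{contig}\t{s}\t{e}\t{species}\n")

    @classmethod
    def from_bed(cls, path) -> "MaskSet":
        """Read a BED written by :meth:`to_bed` (species in the name column)."""
        groups: dict[tuple[str, str], list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                contig, s, e = parts[0], int(parts[1]), int(parts[2])
                species = parts[3] if len(parts) > 3 else "human"
                groups.setdefault((species, contig), []).append((s, e))
        return cls({k: np.array(v, dtype=np.int64) for k, v in groups.items()})


def select_unique(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only uniquely mapped reads (NH = 1); order preserved."""
    return records.loc[records["n_hits"] == 1]


def derive_mask(
    control_records: pd.DataFrame,
    control_species: dict[str, str] | pd.Series,
    pad: int = 0,
) -> MaskSet:
    """Empirical cross-mapping mask from pure-species control samples.

    Every control read mapping to a genome other than its sample's known
    species contributes its interval (padded by ``pad`` bp on each side) to
    the mask on the mapped genome. Overlapping or adjacent intervals are
    merged. An empty mask results iff no cross-species read exists.
    """
    if isinstance(control_species, pd.Series):
        control_species = control_species.to_dict()
    recs = select_unique(control_records)
    samples = recs["sample_id"].astype(str)
    unknown = set(samples.unique()) - set(control_species)
    if unknown:
        raise ValueError(f"control samples with unknown species label: {sorted(unknown)}")
    bad = set(control_species.values()) - set(ENDOGENOUS)
    if bad:
        raise ValueError(f"control species labels must be human/mouse, got {sorted(bad)}")
    own = samples.map(control_species).to_numpy()
    mapped = recs["mapped_species"].astype(str).to_numpy()
    cross = (mapped != own) & np.isin(mapped, ENDOGENOUS)
    sub = recs.loc[cross]
    groups: dict[tuple[str, str], np.ndarray] = {}
    for (species, contig), g in sub.groupby(
        [sub["mapped_species"].astype(str), sub["contig"].astype(str)], sort=True
    ):
        iv = np.column_stack(
            [
                np.maximum(g["start"].to_numpy(np.int64) - pad, 0),
                g["end"].to_numpy(np.int64) + pad,
            ]
        )
        groups[(species, contig)] = iv
    return MaskSet(groups)


def apply_mask(records: pd.DataFrame, mask: MaskSet) -> pd.DataFrame:
    """Drop records overlapping the mask (≥1 bp) on their mapped genome."""
    if mask.is_empty() or len(records) == 0:
        return records
    keep = np.ones(len(records), dtype=bool)
    starts = records["start"].to_numpy(np.int64)
    ends = records["end"].to_numpy(np.int64)
    groups = records.groupby(
        ["mapped_species", "contig"], observed=True, sort=False
    ).indices
    for (sp, ct), idx in groups.items():
        keep[idx] = ~mask.overlaps(str(sp), str(ct), starts[idx], ends[idx])
    return records.loc[keep]


def _species_contig_key(records: pd.DataFrame) -> pd.Categorical:
    """Categorical 'species|contig' key without per-row string building."""
    sp, ct = records["mapped_species"], records["contig"]
    if isinstance(sp.dtype, pd.CategoricalDtype) and isinstance(
        ct.dtype, pd.CategoricalDtype
    ):
        combined = (
            sp.cat.codes.to_numpy(np.int64) * len(ct.cat.categories)
            + ct.cat.codes.to_numpy(np.int64)
        )
        codes, uniques = pd.factorize(combined)
        labels = [
            f"{sp.cat.categories[u // len(ct.cat.categories)]}|"
            f"{ct.cat.categories[u % len(ct.cat.categories)]}"
            for u in uniques
        ]
        return pd.Categorical.from_codes(codes, categories=labels)
    return pd.Categorical(sp.astype(str) + "|" + ct.astype(str))


def _check_annotation(genes: pd.DataFrame) -> None:
    dup = genes["gene_id"][genes["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"gene annotation has duplicated gene ids: {sorted(set(dup))[:5]}")


def count_by_gene(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Union-mode gene counting, split by species through the annotation.

    A read contributes one count to a gene iff it overlaps exactly one gene on
    its mapped genome; reads overlapping zero or several genes are discarded
    as ambiguous. Returns a genes × samples integer matrix covering every
    annotated gene (zeros included); the annotation provides species/biotype.
    """
    _check_annotation(genes)
    all_samples = (
        records[sample_col].cat.categories.tolist()
        if isinstance(records[sample_col].dtype, pd.CategoricalDtype)
        else sorted(records[sample_col].unique())
    )
    empty = pd.DataFrame(
        0, index=pd.Index(genes["gene_id"], name="gene_id"), columns=all_samples, dtype=np.int64
    )
    if len(records) == 0:
        return empty
    # species-qualified chromosome keys keep the two genomes separate
    reads_df = pd.DataFrame(
        {
            "Chromosome": _species_contig_key(records),
            "Start": records["start"].to_numpy(np.int64),
            "End": records["end"].to_numpy(np.int64),
            "sample": records[sample_col].astype(str).to_numpy(),
            "ridx": np.arange(len(records)),
        }
    )
    genes_df = pd.DataFrame(
        {
            "Chromosome": genes["species"].astype(str) + "|" + genes["contig"].astype(str),
            "Start": genes["start"].to_numpy(np.int64),
            "End": genes["end"].to_numpy(np.int64),
            "gene_id": genes["gene_id"].to_numpy(),
        }
    )
    joined = pr.PyRanges(reads_df).join(pr.PyRanges(genes_df)).df
    if len(joined) == 0:
        return empty
    hits_per_read = joined.groupby("ridx")["gene_id"].transform("size")
    unambiguous = joined.loc[hits_per_read == 1]
    tallies = (
        unambiguous.groupby(["gene_id", "sample"], sort=False).size().unstack(fill_value=0)
    )
    counts = empty.add(tallies.reindex(index=empty.index, columns=all_samples, fill_value=0),
                       fill_value=0).astype(np.int64)
    return counts


def count_species_totals(records: pd.DataFrame, sample_col: str = "sample_id") -> pd.DataFrame:
    """Per-sample totals of reads mapped to each genome and to each spike.

    Spike reads are totalled per spike contig (column named after the spike);
    endogenous reads per genome appear under 'human' and 'mouse'. These totals
    feed the spike-anchored concentration estimator, which uses all reads
    mapped to a genome, not only gene-assigned ones.
    """
    sizes = (
        records.groupby([sample_col, "mapped_species", "contig"], observed=True)
        .size()
        .reset_index(name="n")
    )
    what = np.where(
        sizes["mapped_species"].astype(str) == "spike",
        sizes["contig"].astype(str),
        sizes["mapped_species"].astype(str),
    )
    sizes["what"] = what
    sizes["sample"] = sizes[sample_col].astype(str)
    out = sizes.groupby(["sample", "what"])["n"].sum().unstack(fill_value=0)
    for col in ENDOGENOUS:
        if col not in out.columns:
            out[col] = 0
    return out
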