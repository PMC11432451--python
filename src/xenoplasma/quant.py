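"""Spike-anchored absolute cfRNA quantification and per-sample summary metrics.

Plasma cfRNA mass cannot be read off sequencing counts alone: library size is
arbitrary. A synthetic spike (ERCC/Sequin) of known mass added to the sample
anchors the scale — the endogenous mass is the spike mass multiplied by the
ratio of endogenous to spike reads, and dividing by the plasma volume yields a
concentration in pg/mL. This module implements that estimator together with
species fractions, detected-gene counts, CPM normalization, the caliper tumor
volume formula, and Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpikeSpec",
    "spike_mass",
    "cfrna_concentration",
    "species_fraction",
    "detected_genes",
    "cpm_normalize",
    "tumor_volume",
    "is_endpoint",
    "spearman",
    "UndefinedConcentrationError",
]

#: humane-endpoint threshold for caliper tumor volume, mm^3
ENDPOINT_VOLUME_MM3 = 1500.0


class UndefinedConcentrationError(ValueError):
    """Raised when a sample has no spike reads and its concentration is undefined."""


@dataclass(frozen=True)
class SpikeSpec:
    """A synthetic RNA spike added at known mass.

    mass = stock_concentration (pg/µL) × dilution × volume_added (µL).
    """

    spike_id: str
    stock_concentration: float  # pg/µL
    dilution: float  # dimensionless, e.g. 1/200000
    volume_added: float  # µL

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.stock_concentration)
            and np.isfinite(self.dilution)
            and np.isfinite(self.volume_added)
        ):
            raise ValueError("spike specification fields must be finite")
        if self.stock_concentration <= 0 or self.dilution <= 0 or self.volume_added <= 0:
            raise ValueError(
                f"spike {self.spike_id!r}: stock_concentration, dilution and "
                "volume_added must all be positive"
            )

    @property
    def mass_pg(self) -> float:
        return self.stock_concentration * self.dilution * self.volume_added


def spike_mass(spec: SpikeSpec) -> float:
    """Known input mass (pg) of a spike: stock concentration × dilution × volume."""
    return spec.mass_pg


def cfrna_concentration(
    endogenous_reads: float,
    spike_reads: float,
    spike_mass_pg: float,
    plasma_volume_ml: float,
) -> float:
    """Absolute cfRNA concentration (pg/mL) anchored on a spike of known mass.

    Multiplies the spike mass by the ratio of reads mapped to the endogenous
    genome over reads mapped to the spike, then divides by the plasma volume.
    Computed separately per species (human or murine endogenous reads).

    Raises
    ------
    UndefinedConcentrationError
        If ``spike_reads`` is zero — the sample must be flagged, not zeroed.
    """
    if spike_reads < 0 or endogenous_reads < 0:
        raise ValueError("read counts must be non-negative")
    if spike_mass_pg <= 0:
        raise ValueError("spike mass must be positive")
    if plasma_volume_ml <= 0:
        raise ValueError("plasma volume must be positive")
    if spike_reads == 0:
        raise UndefinedConcentrationError(
            "no spike reads in sample: concentration undefined"
        )
    return spike_mass_pg * (endogenous_reads / spike_reads) / plasma_volume_ml


def _species_sums(counts: pd.DataFrame, species: pd.Series, sample: str) -> pd.Series:
    col = counts[sample]
    return col.groupby(species.reindex(counts.index)).sum()


def species_fraction(counts: pd.DataFrame, species: pd.Series, sample: str) -> float:
    """Fraction of endogenous counts that is human; spikes excluded.

    Parameters
    ----------
    counts : genes × samples integer matrix.
    species : per-gene label in {"human", "mouse", "spike"} aligned to counts rows.
    sample : column name.
    """
    sums = _species_sums(counts, species, sample)
    human = float(sums.get("human", 0))
    mouse = float(sums.get("mouse", 0))
    total = human + mouse
    if total == 0:
        raise ValueError(f"sample {sample!r} has no endogenous reads")
    return human / total


def detected_genes(
    counts: pd.DataFrame,
    species: pd.Series,
    sample: str,
    which_species: str,
    min_count: int = 1,
) -> int:
    """Number of genes of one species with at least ``min_count`` reads."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    sp = species.reindex(counts.index)
    if which_species not in set(sp.unique()):
        raise ValueError(f"unknown species tag {which_species!r}")
    sub = counts.loc[sp == which_species, sample]
    return int((sub >= min_count).sum())


def cpm_normalize(
    counts: pd.DataFrame,
    species: pd.Series | None = None,
    per_species: bool = False,
) -> pd.DataFrame:
    """Counts-per-million normalization; no log transform is applied.

    With ``per_species=True`` each species block of each column is scaled to
    sum to 1e6 within that block (the normalization universe is the species).
    """
    counts = counts.astype(float)
    if per_species:
        if species is None:
            raise ValueError("per_species=True requires a species annotation")
        out = counts.copy()
        sp = species.reindex(counts.index)
        for tag in sp.dropna().unique():
            block = counts.loc[sp == tag]
            sums = block.sum(axis=0)
            if (sums == 0).any():
                bad = sums.index[sums == 0].tolist()
                raise ValueError(f"zero-sum {tag} block in samples {bad}")
            out.loc[sp == tag] = block * 1e6 / sums
        return out
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0].tolist()
        raise ValueError(f"zero-sum columns: {bad}")
    return counts * 1e6 / sums


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = L·W²/2 (mm³); L is the longer axis."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper measurements must be non-negative")
    return length_mm * width_mm**2 / 2.0


def is_endpoint(volume_mm3: float) -> bool:
    """Humane endpoint: tumor volume strictly greater than 1500 mm³."""
    return volume_mm3 > ENDPOINT_VOLUME_MM3


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (R, p) with p from the large-sample t approximation. A constant
    vector makes R undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman R undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)
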