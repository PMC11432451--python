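"""Synthetic humanized-PDTX cfRNA cohorts with recorded ground truth.

Emulates the design of a longitudinal plasma liquid-biopsy study in a
patient-derived-xenograft (PDTX) lymphoma mouse model: cohorts of humanized
(HIS) and non-humanized mice, with or without xenograft, under PBS or
immunochemotherapy, drawn at fixed timepoints. Each low-volume plasma draw
yields an alignment-record table of reads mapped to a combined human+mouse
reference plus synthetic spikes, with per-read true species recorded, so the
whole downstream pipeline (read splitting, spike quantification, differential
abundance, signature classification, repertoire overlap, deconvolution) can be
validated against known truth without any external data.

Model in brief
--------------
* Tumor growth is Gompertz, V(t) = K·exp(ln(V0/K)·e^{-a·t}), with lognormal
  per-mouse rate heterogeneity; a humanized immune system clears the tumor in
  a Bernoulli fraction of untreated mice; treatment switches growth to
  exponential decay unless the mouse is flagged resistant; a mouse is
  sacrificed at the first day its volume exceeds 1500 mm³ (caliper V=L·W²/2).
* Plasma human cfRNA mass is humanization_baseline·[humanized] +
  tumor_mass_coeff·V(t), on top of a murine background and spikes of known
  mass; reads are allocated to sources proportional to mass.
* Per-gene counts are gamma–Poisson (negative binomial marginals, common
  dispersion φ), with gene weights renormalized within species so species
  mass shares are exact.
* Cross-species misalignment is concentrated in paired 200-bp hotspot windows
  (fixed per seed); reads overlapping a hotspot are re-mapped uniquely
  (n_hits=1) into the partner genome's window at a configurable rate — this is
  exactly the artifact the empirical masking stage must catch. A separate
  fraction of reads is multi-mapping (n_hits>1).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .celldeconv import CELL_TYPES, PLASMA_CELL_MARKERS, synthetic_basis
from .quant import SpikeSpec

__all__ = [
    "Arm",
    "Timepoint",
    "GrowthParams",
    "ExpressionParams",
    "CrossmapParams",
    "SimConfig",
    "SimTruth",
    "Cohort",
    "default_config",
    "simulate_growth",
    "simulate_cohort",
    "simulate_controls",
    "write_fixture",
    "read_fixture",
    "SIGNATURE_GENES",
]

#: the 8-gene tumor signature planted in the human tumor expression profile
SIGNATURE_GENES = (
    "PHF14",
    "PELP1",
    "RPL7L1",
    "HPRT1",
    "RELN",
    "RNU1-75P",
    "RNU5A-8P",
    "RNVU1-19",
)

TREATMENTS = ("PBS", "R-CHOP", "huCD20-Fc-AFN-CHOP")
TIMEPOINT_LABELS = (
    "pre_humanization",
    "pre_PDTX",
    "pre_treatment",
    "post_treatment",
    "sacrifice",
)

GENE_LEN = 1500  # bp, synthetic gene body length
GENE_GAP = 500  # bp between genes
READ_LEN = 100  # bp
HOTSPOT_LEN = 200  # bp, per design: fixed windows of cross-species misalignment
SPIKE_CONTIG_LEN = 1000  # bp
ENDPOINT_VOLUME = 1500.0  # mm^3, humane endpoint (V = L*W^2/2)

#: resting circulating immune composition used for the humanization component
BASE_IMMUNE_FRACTIONS = {
    "B cell": 0.30,
    "plasma cell": 0.02,
    "CD4 T cell": 0.20,
    "CD8 T cell": 0.13,
    "NK cell": 0.05,
    "monocyte": 0.10,
    "macrophage": 0.05,
    "dendritic cell": 0.03,
    "neutrophil": 0.07,
    "erythrocyte": 0.02,
    "platelet": 0.02,
    "hepatocyte": 0.01,
}

B_DEPLETION_FACTOR = 0.15  # immunochemotherapy depletes circulating B cells
TUMOR_PLASMA_CELL_WEIGHT = 0.3  # share of tumor profile on plasma-cell markers
SIGNATURE_FOLD = 40.0  # enrichment of signature genes within the tumor profile


@dataclass(frozen=True)
class Arm:
    humanized: bool
    xenografted: bool
    treatment: str

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def label(self) -> str:
        h = "HIS" if self.humanized else "nonHIS"
        x = "PDTX" if self.xenografted else "nonPDTX"
        return f"{h}-{x}-{self.treatment}"


@dataclass(frozen=True)
class Timepoint:
    label: str
    day: int

    def __post_init__(self):
        if self.label not in TIMEPOINT_LABELS:
            raise ValueError(f"unknown timepoint label {self.label!r}")


@dataclass(frozen=True)
class GrowthParams:
    v0: float = 20.0  # mm^3 engrafted volume
    carrying_capacity: float = 2000.0  # mm^3
    rate: float = 0.06  # /day Gompertz rate
    rate_dispersion: float = 0.15  # lognormal sigma of per-mouse rate
    immune_control_prob: float = 0.3  # HIS PBS mice clearing the graft
    treatment_decay: float = 0.12  # /day exponential clearance under therapy
    treatment_start_day: int = 14
    treatment_resistant_prob: float = 0.1

    def __post_init__(self):
        vals = [
            self.v0,
            self.carrying_capacity,
            self.rate,
            self.rate_dispersion,
            self.treatment_decay,
        ]
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("growth parameters must be finite and non-negative")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying capacity must be positive")
        for p in (self.immune_control_prob, self.treatment_resistant_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ExpressionParams:
    n_mouse_genes: int = 2000
    n_human_tumor_genes: int = 300
    n_human_immune_genes: int = 500
    dispersion: float = 0.3  # NB dispersion phi shared across genes
    library_size_mean: float = 120_000.0
    library_size_cv: float = 0.3

    def __post_init__(self):
        if self.n_human_tumor_genes < len(SIGNATURE_GENES):
            raise ValueError("need at least 8 human tumor genes for the signature")
        if self.n_human_immune_genes < len(CELL_TYPES):
            raise ValueError("need at least one immune gene per basis cell type")
        if self.n_mouse_genes < 1:
            raise ValueError("need at least one mouse gene")
        if self.dispersion < 0 or self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ValueError("invalid expression noise parameters")


@dataclass(frozen=True)
class CrossmapParams:
    n_hotspots: int = 50  # paired 200-bp windows per genome
    hotspot_misassign_rate: float = 0.3
    multimap_fraction: float = 0.05

    def __post_init__(self):
        if self.n_hotspots < 0:
            raise ValueError("n_hotspots must be >= 0")
        if not 0.0 <= self.hotspot_misassign_rate < 1.0:
            raise ValueError("hotspot_misassign_rate must be in [0, 1)")
        if not 0.0 <= self.multimap_fraction <= 1.0:
            raise ValueError("multimap_fraction must be in [0, 1]")


def _default_arms() -> tuple[Arm, ...]:
    return (
        Arm(True, False, "PBS"),
        Arm(False, True, "PBS"),
        Arm(False, True, "R-CHOP"),
        Arm(False, True, "huCD20-Fc-AFN-CHOP"),
        Arm(True, True, "PBS"),
        Arm(True, True, "R-CHOP"),
        Arm(True, True, "huCD20-Fc-AFN-CHOP"),
    )


def _default_timepoints() -> tuple[Timepoint, ...]:
    return (
        Timepoint("pre_humanization", -14),
        Timepoint("pre_PDTX", 0),
        Timepoint("pre_treatment", 14),
        Timepoint("post_treatment", 28),
        Timepoint("sacrifice", 42),
    )


def _default_spikes() -> tuple[SpikeSpec, ...]:
    # Sequin mix A at 1/260,000 and ERCC mix at 1/200,000, 2 µL each; the
    # effective per-spike stock concentrations are config inputs.
    return (
        SpikeSpec("ERCC-00130", 5200.0, 1.0 / 200_000, 2.0),
        SpikeSpec("SEQUIN-MIX-A", 2600.0, 1.0 / 260_000, 2.0),
    )


@dataclass(frozen=True)
class SimConfig:
    n_mice_per_arm: int = 7
    arms: tuple[Arm, ...] = field(default_factory=_default_arms)
    timepoints: tuple[Timepoint, ...] = field(default_factory=_default_timepoints)
    growth: GrowthParams = field(default_factory=GrowthParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    humanization_baseline_pg_per_ml: float = 3.5
    murine_baseline_pg_per_ml: float = 600.0
    tumor_mass_coeff: float = 0.012  # pg·mL⁻¹ per mm³ of tumor
    crossmap: CrossmapParams = field(default_factory=CrossmapParams)
    spikes: tuple[SpikeSpec, ...] = field(default_factory=_default_spikes)
    plasma_volume_ml: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_mice_per_arm < 1:
            raise ValueError("n_mice_per_arm must be >= 1")
        if len(self.arms) == 0:
            raise ValueError("arm list must be non-empty")
        days = [tp.day for tp in self.timepoints]
        if len(self.timepoints) == 0 or days != sorted(days) or len(set(days)) != len(days):
            raise ValueError("timepoints must be non-empty and strictly increasing in day")
        for v in (
            self.humanization_baseline_pg_per_ml,
            self.murine_baseline_pg_per_ml,
            self.tumor_mass_coeff,
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError("masses and coefficients must be finite and >= 0")
        if self.plasma_volume_ml <= 0:
            raise ValueError("plasma volume must be positive")


def default_config(**overrides) -> SimConfig:
    """The default study-design configuration, with optional field overrides."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


# ---------------------------------------------------------------------------
# tumor growth


def simulate_growth(
    v0: float,
    carrying_capacity: float,
    rate: float,
    days,
    *,
    treated: bool = False,
    treatment_start_day: float = 14,
    treatment_decay: float = 0.12,
    immune_controlled: bool = False,
    resistant: bool = False,
    endpoint_volume: float = ENDPOINT_VOLUME,
) -> tuple[np.ndarray, np.ndarray]:
    """Gompertz tumor-volume trajectory, truncated at the humane endpoint.

    V(t) = K·exp(ln(V0/K)·e^{-a·t}); zero throughout for non-engrafted
    (v0 = 0) or immune-controlled mice. In treated, non-resistant mice the
    volume decays exponentially at ``treatment_decay`` after
    ``treatment_start_day``. The trajectory stops at the first day the volume
    exceeds ``endpoint_volume`` (the mouse is sacrificed).

    Returns (days, volumes) as arrays of equal (possibly truncated) length.
    """
    for v in (v0, carrying_capacity, rate, treatment_start_day, treatment_decay):
        if not np.isfinite(v):
            raise ValueError("growth parameters must be finite")
    if v0 < 0 or carrying_capacity <= 0 or rate < 0:
        raise ValueError("require v0 >= 0, K > 0, rate >= 0")
    t = np.asarray(days, dtype=float)
    if immune_controlled or v0 == 0:
        return t, np.zeros_like(t)
    gomp = lambda tt: carrying_capacity * np.exp(
        np.log(v0 / carrying_capacity) * np.exp(-rate * tt)
    )
    vol = gomp(t)
    if treated and not resistant:
        after = t > treatment_start_day
        v_start = gomp(np.asarray(treatment_start_day, dtype=float))
        vol = np.where(
            after, v_start * np.exp(-treatment_decay * (t - treatment_start_day)), vol
        )
    over = np.nonzero(vol > endpoint_volume)[0]
    if over.size:
        stop = over[0] + 1  # include the first day past the endpoint
        t, vol = t[:stop], vol[:stop]
    return t, vol


def _caliper_from_volume(volume: float, aspect: float = 1.5) -> tuple[float, float]:
    """Invert V = L·W²/2 under a fixed L/W aspect ratio (L the longer axis)."""
    if volume <= 0:
        return 0.0, 0.0
    width = (2.0 * volume / aspect) ** (1.0 / 3.0)
    return aspect * width, width


def _assemble_alignments(named_frames: list[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Concatenate per-sample read frames, adding a categorical sample_id."""
    cols = ["sample_id", "read_id", "mapped_species", "contig", "start", "end",
            "n_hits", "true_species"]
    if not named_frames:
        return pd.DataFrame(columns=cols)
    sample_ids = [sid for sid, _ in named_frames]
    lengths = np.array([len(f) for _, f in named_frames])
    out = pd.concat([f for _, f in named_frames], ignore_index=True)
    codes = np.repeat(np.arange(len(sample_ids)), lengths)
    out.insert(
        0,
        "sample_id",
        pd.Categorical.from_codes(codes, categories=sample_ids),
    )
    return out


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    samples: pd.DataFrame  # per-sample masses, volumes, fractions, library size
    cell_fractions: pd.DataFrame  # samples × cell types, true mixture weights
    hotspots: pd.DataFrame  # paired cross-mapping windows
    signature_multipliers: pd.Series  # planted fold enrichment per signature gene


@dataclass
class Cohort:
    alignments: pd.DataFrame
    meta: pd.DataFrame
    truth: SimTruth
    genes: pd.DataFrame  # gene_id, species, contig, start, end, biotype
    config: SimConfig


def _gene_annotation(expr: ExpressionParams, basis_genes) -> pd.DataFrame:
    """Lay out synthetic genes on 4 contigs per genome, 0-based half-open."""

    def lay(gene_ids, species, prefix, biotypes):
        n_contigs = 4
        rows = []
        pos = [0] * n_contigs
        for i, g in enumerate(gene_ids):
            c = i % n_contigs
            start = pos[c]
            rows.append((g, species, f"{prefix}{c + 1}", start, start + GENE_LEN, biotypes[i]))
            pos[c] = start + GENE_LEN + GENE_GAP
        return rows

    mouse_ids = [f"Mgene{i:04d}" for i in range(expr.n_mouse_genes)]
    n_extra = expr.n_human_tumor_genes - len(SIGNATURE_GENES)
    tumor_ids = list(SIGNATURE_GENES) + [f"HTUM{i:04d}" for i in range(n_extra)]

    def biotype_of(name: str) -> str:
        if name.startswith(("RNU", "RNVU")):
            return "snRNA"
        if name.startswith("HTUM") and int(name[4:]) % 5 == 0:
            return "lncRNA"
        return "protein_coding"

    rows = []
    rows += lay(mouse_ids, "mouse", "m", ["protein_coding"] * len(mouse_ids))
    human_ids = tumor_ids + list(basis_genes)
    rows += lay(human_ids, "human", "h", [biotype_of(g) for g in human_ids])
    return pd.DataFrame(
        rows, columns=["gene_id", "species", "contig", "start", "end", "biotype"]
    )


def _draw_hotspots(genes: pd.DataFrame, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Pick n paired (mouse, human) 200-bp windows inside gene bodies."""
    mouse = genes[genes.species == "mouse"]
    human = genes[genes.species == "human"]
    n = min(n, len(mouse), len(human))
    if n == 0:
        return pd.DataFrame(
            columns=[
                "pair", "mouse_gene", "mouse_contig", "mouse_start", "mouse_end",
                "human_gene", "human_contig", "human_start", "human_end",
            ]
        )
    mi = rng.choice(len(mouse), size=n, replace=False)
    hi = rng.choice(len(human), size=n, replace=False)
    off_m = rng.integers(0, GENE_LEN - HOTSPOT_LEN + 1, size=n)
    off_h = rng.integers(0, GENE_LEN - HOTSPOT_LEN + 1, size=n)
    mrows, hrows = mouse.iloc[mi], human.iloc[hi]
    return pd.DataFrame(
        {
            "pair": np.arange(n),
            "mouse_gene": mrows.gene_id.to_numpy(),
            "mouse_contig": mrows.contig.to_numpy(),
            "mouse_start": mrows.start.to_numpy() + off_m,
            "mouse_end": mrows.start.to_numpy() + off_m + HOTSPOT_LEN,
            "human_gene": hrows.gene_id.to_numpy(),
            "human_contig": hrows.contig.to_numpy(),
            "human_start": hrows.start.to_numpy() + off_h,
            "human_end": hrows.start.to_numpy() + off_h + HOTSPOT_LEN,
        }
    )


SPECIES_CATEGORIES = ("mouse", "human", "spike")


class _Profiles:
    """Cohort-level expression profiles and hotspot lookups (fixed per seed)."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        expr = config.expression
        n_markers = max(1, expr.n_human_immune_genes // (2 * len(CELL_TYPES)))
        self.basis = synthetic_basis(
            n_genes=expr.n_human_immune_genes, n_markers_per_type=n_markers
        )
        self.genes = _gene_annotation(expr, self.basis.index)
        gsub = self.genes.set_index("gene_id")
        self.mouse_genes = gsub[gsub.species == "mouse"]
        self.human_genes = gsub[gsub.species == "human"]
        # compact per-read encoding: shared contig category list
        self.contig_categories = list(
            dict.fromkeys(self.genes.contig.tolist())
        ) + [s.spike_id for s in config.spikes]
        self._contig_code = {c: i for i, c in enumerate(self.contig_categories)}
        self.contig_codes = {
            "mouse": self.mouse_genes.contig.map(self._contig_code).to_numpy(np.int16),
            "human": self.human_genes.contig.map(self._contig_code).to_numpy(np.int16),
        }

        # murine background profile
        p = rng.lognormal(0.0, 1.5, size=len(self.mouse_genes))
        self.mouse_profile = p / p.sum()

        # human tumor profile: lognormal base over tumor genes, signature
        # genes strongly enriched, plus a plasma-cell-like component on the
        # basis markers (the xenograft is a B-cell lymphoma)
        human_ids = self.human_genes.index.to_numpy()
        n_tumor = expr.n_human_tumor_genes
        tum = rng.lognormal(0.0, 1.0, size=n_tumor)
        mult = pd.Series(1.0, index=human_ids[:n_tumor])
        for g in SIGNATURE_GENES:
            tum[list(human_ids[:n_tumor]).index(g)] *= SIGNATURE_FOLD
            mult[g] = SIGNATURE_FOLD
        self.signature_multipliers = mult[list(SIGNATURE_GENES)]
        tumor_part = np.zeros(len(human_ids))
        tumor_part[:n_tumor] = tum / tum.sum() * (1.0 - TUMOR_PLASMA_CELL_WEIGHT)
        plasma_col = self.basis["plasma cell"].to_numpy()
        tumor_part[n_tumor:] += (
            plasma_col / plasma_col.sum() * TUMOR_PLASMA_CELL_WEIGHT
        )
        self.tumor_profile = tumor_part
        self.n_tumor = n_tumor
        self.human_ids = human_ids

        self.hotspots = _draw_hotspots(self.genes, config.crossmap.n_hotspots, rng)
        # per-gene hotspot lookup arrays aligned with each species gene table
        # (row order), -1 marking genes without a hotspot window
        self.hotspot_arrays: dict[str, dict[str, np.ndarray]] = {}
        for species, tbl, own, partner in (
            ("mouse", self.mouse_genes, "mouse", "human"),
            ("human", self.human_genes, "human", "mouse"),
        ):
            n = len(tbl)
            arr = {
                "hs_start": np.full(n, -1, dtype=np.int64),
                "hs_end": np.full(n, -1, dtype=np.int64),
                "p_start": np.full(n, -1, dtype=np.int64),
                "p_contig_idx": np.full(n, -1, dtype=np.int64),
            }
            partner_contigs: list[int] = []
            if len(self.hotspots):
                pos = {g: i for i, g in enumerate(tbl.index)}
                for _, r in self.hotspots.iterrows():
                    i = pos[r[f"{own}_gene"]]
                    arr["hs_start"][i] = r[f"{own}_start"]
                    arr["hs_end"][i] = r[f"{own}_end"]
                    arr["p_start"][i] = r[f"{partner}_start"]
                    arr["p_contig_idx"][i] = len(partner_contigs)
                    partner_contigs.append(self._contig_code[r[f"{partner}_contig"]])
            arr["p_contig_codes"] = np.array(partner_contigs, dtype=np.int16)
            arr["partner_species_code"] = SPECIES_CATEGORIES.index(partner)
            self.hotspot_arrays[species] = arr

    def immune_profile(self, fractions: dict[str, float]) -> np.ndarray:
        """Human-gene proportions of a circulating immune mixture."""
        f = np.array([fractions.get(c, 0.0) for c in self.basis.columns])
        mix = self.basis.to_numpy() @ f
        out = np.zeros(len(self.human_ids))
        out[self.n_tumor :] = mix / mix.sum() if mix.sum() > 0 else 0.0
        return out


def _immune_fractions(arm: Arm, day: int, growth: GrowthParams) -> dict[str, float]:
    f = dict(BASE_IMMUNE_FRACTIONS)
    if arm.treatment != "PBS" and day > growth.treatment_start_day:
        f["B cell"] *= B_DEPLETION_FACTOR
        s = sum(f.values())
        f = {k: v / s for k, v in f.items()}
    return f


def _expand_reads(
    counts: np.ndarray,
    gene_start: np.ndarray,
    gene_len: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-read start positions for per-gene counts (uniform within gene)."""
    starts = np.repeat(gene_start, counts)
    offs = rng.integers(0, gene_len - READ_LEN + 1, size=starts.size)
    return np.repeat(np.arange(len(counts)), counts), starts + offs


def _sample_reads(
    prof: _Profiles,
    config: SimConfig,
    lib_size: float,
    mass_by_source: dict[str, float],
    human_prop: np.ndarray,
    mouse_weights: np.ndarray,
    human_weights: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit one sample's alignment records (species, locus, NH, true species).

    Species and contigs are stored as pandas categoricals built from compact
    integer codes so tens of millions of reads stay memory-lean.
    """
    total_mass = sum(mass_by_source.values())
    chunks: list[tuple[np.ndarray, np.ndarray, np.ndarray, int]] = []
    # each chunk: (species_code per read, contig_code, start, true_species_code)

    def emit_endogenous(species, gene_tbl, base_prop, gamma_w, mass):
        if mass <= 0:
            return
        w = base_prop * gamma_w
        if w.sum() == 0:
            return
        lam = lib_size * (mass / total_mass) * (w / w.sum())
        counts = rng.poisson(lam)
        gidx, starts = _expand_reads(counts, gene_tbl.start.to_numpy(), GENE_LEN, rng)
        if starts.size == 0:
            return
        sp_code = SPECIES_CATEGORIES.index(species)
        contig_code = prof.contig_codes[species][gidx]
        species_code = np.full(starts.size, sp_code, dtype=np.int8)
        starts = starts.astype(np.int32)

        # hotspot misassignment: reads overlapping their gene's window jump
        # into the partner genome's paired window, still uniquely mapped
        rate = config.crossmap.hotspot_misassign_rate
        hsa = prof.hotspot_arrays.get(species)
        if rate > 0 and hsa is not None and len(hsa["p_contig_codes"]):
            hs_s, hs_e = hsa["hs_start"][gidx], hsa["hs_end"][gidx]
            overlaps = (hs_s >= 0) & (starts < hs_e) & (starts + READ_LEN > hs_s)
            if overlaps.any():
                hit = np.nonzero(overlaps)[0]
                flip = hit[rng.random(hit.size) < rate]
                if flip.size:
                    species_code[flip] = hsa["partner_species_code"]
                    contig_code = contig_code.copy()
                    contig_code[flip] = hsa["p_contig_codes"][hsa["p_contig_idx"][gidx[flip]]]
                    starts[flip] = (
                        hsa["p_start"][gidx[flip]]
                        + rng.integers(0, HOTSPOT_LEN - READ_LEN + 1, size=flip.size)
                    ).astype(np.int32)
        chunks.append((species_code, contig_code, starts, sp_code))

    emit_endogenous("mouse", prof.mouse_genes, prof.mouse_profile, mouse_weights,
                    mass_by_source.get("mouse", 0.0))
    emit_endogenous("human", prof.human_genes, human_prop, human_weights,
                    mass_by_source.get("human", 0.0))

    # spikes: Poisson counts proportional to known mass, one contig per spike
    spike_code = SPECIES_CATEGORIES.index("spike")
    for spec in config.spikes:
        lam = lib_size * spec.mass_pg / total_mass
        n = rng.poisson(lam)
        if n == 0:
            continue
        starts = rng.integers(0, SPIKE_CONTIG_LEN - READ_LEN + 1, size=n).astype(np.int32)
        ccode = np.full(n, prof._contig_code[spec.spike_id], dtype=np.int16)
        chunks.append((np.full(n, spike_code, dtype=np.int8), ccode, starts, spike_code))

    if chunks:
        species_code = np.concatenate([c[0] for c in chunks])
        contig_code = np.concatenate([c[1] for c in chunks])
        start = np.concatenate([c[2] for c in chunks])
        true_code = np.concatenate(
            [np.full(len(c[0]), c[3], dtype=np.int8) for c in chunks]
        )
    else:
        species_code = np.empty(0, dtype=np.int8)
        contig_code = np.empty(0, dtype=np.int16)
        start = np.empty(0, dtype=np.int32)
        true_code = np.empty(0, dtype=np.int8)

    n = len(start)
    n_hits = np.ones(n, dtype=np.int16)
    mm = rng.random(n) < config.crossmap.multimap_fraction
    mm &= species_code == true_code  # misassigned reads stay uniquely mapped
    n_hits[mm] = rng.integers(2, 9, size=int(mm.sum()))

    cats = list(SPECIES_CATEGORIES)
    return pd.DataFrame(
        {
            "read_id": np.arange(n, dtype=np.int32),
            "mapped_species": pd.Categorical.from_codes(species_code, categories=cats),
            "contig": pd.Categorical.from_codes(
                contig_code, categories=prof.contig_categories
            ),
            "start": start,
            "end": start + READ_LEN,
            "n_hits": n_hits,
            "true_species": pd.Categorical.from_codes(true_code, categories=cats),
        }
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full longitudinal cohort; deterministic under config.seed."""
    ss = np.random.SeedSequence(config.seed)
    s_design, s_reads = ss.spawn(2)
    rng_design = np.random.default_rng(s_design)
    rng_reads = np.random.default_rng(s_reads)

    prof = _Profiles(config, rng_design)
    growth = config.growth
    expr = config.expression

    meta_rows, truth_rows, frac_rows, align_frames = [], [], [], []
    sigma_lib = np.sqrt(np.log1p(expr.library_size_cv**2))

    for arm in config.arms:
        for m in range(config.n_mice_per_arm):
            mouse_id = f"{arm.label}_m{m + 1}"
            rate = growth.rate * rng_design.lognormal(0.0, growth.rate_dispersion)
            immune_controlled = bool(
                arm.humanized
                and arm.xenografted
                and arm.treatment == "PBS"
                and rng_design.random() < growth.immune_control_prob
            )
            resistant = bool(
                arm.treatment != "PBS"
                and rng_design.random() < growth.treatment_resistant_prob
            )
            tps = [
                tp
                for tp in config.timepoints
                if arm.humanized or tp.label != "pre_humanization"
            ]
            days = np.array([max(tp.day, 0) for tp in tps], dtype=float)
            v0 = growth.v0 if arm.xenografted else 0.0
            # volume at every draw day (pre-engraftment draws see volume 0)
            _, vol_full = simulate_growth(
                v0 if v0 > 0 else 0.0,
                growth.carrying_capacity,
                rate,
                days,
                treated=arm.treatment != "PBS",
                treatment_start_day=growth.treatment_start_day,
                treatment_decay=growth.treatment_decay,
                immune_controlled=immune_controlled,
                resistant=resistant,
                endpoint_volume=np.inf,  # truncation handled per draw below
            )
            vols = np.where(np.array([tp.day for tp in tps]) < 0, 0.0, vol_full)

            # find sacrifice day (first day volume exceeds the endpoint)
            sac_day = None
            scan = np.arange(0.0, max(tp.day for tp in tps) + 1.0)
            _, vscan = simulate_growth(
                v0, growth.carrying_capacity, rate, scan,
                treated=arm.treatment != "PBS",
                treatment_start_day=growth.treatment_start_day,
                treatment_decay=growth.treatment_decay,
                immune_controlled=immune_controlled,
                resistant=resistant,
                endpoint_volume=np.inf,
            )
            over = np.nonzero(vscan > ENDPOINT_VOLUME)[0]
            if over.size:
                sac_day = float(scan[over[0]])

            # per-mouse design draws are consumed before count generation so
            # expected masses depend only on design randomness
            lib_sizes = np.maximum(
                rng_design.lognormal(
                    np.log(expr.library_size_mean) - sigma_lib**2 / 2.0,
                    sigma_lib,
                    size=len(tps),
                ),
                100.0,
            )
            phi = expr.dispersion
            gshape = 1.0 / phi if phi > 0 else None

            for k, tp in enumerate(tps):
                day = float(tp.day)
                vol = float(vols[k])
                if sac_day is not None:
                    if tp.label == "sacrifice" or tp is tps[-1]:
                        day = min(day, sac_day)
                        idx = int(day)
                        vol = float(vscan[idx])
                    elif tp.day >= sac_day:
                        continue  # draw never happened; mouse was sacrificed
                sample_id = f"{mouse_id}_{tp.label}"
                humanized_active = arm.humanized and tp.label != "pre_humanization"
                m_h = (
                    config.humanization_baseline_pg_per_ml * humanized_active
                    + config.tumor_mass_coeff * vol
                ) * config.plasma_volume_ml
                m_m = config.murine_baseline_pg_per_ml * config.plasma_volume_ml
                m_spike = sum(s.mass_pg for s in config.spikes)
                m_tum = config.tumor_mass_coeff * vol * config.plasma_volume_ml
                m_imm = m_h - m_tum

                ifr = _immune_fractions(arm, day, growth)
                human_prop = (
                    (m_imm * prof.immune_profile(ifr) + m_tum * prof.tumor_profile)
                    / m_h
                    if m_h > 0
                    else np.zeros(len(prof.human_ids))
                )
                if m_h > 0:
                    tf = {
                        c: (m_imm * ifr[c] + (m_tum if c == "plasma cell" else 0.0)) / m_h
                        for c in CELL_TYPES
                    }
                else:
                    tf = {c: np.nan for c in CELL_TYPES}

                lib = float(lib_sizes[k])
                if gshape is not None:
                    mouse_w = rng_design.gamma(gshape, phi, size=len(prof.mouse_genes))
                    human_w = rng_design.gamma(gshape, phi, size=len(prof.human_ids))
                else:
                    mouse_w = np.ones(len(prof.mouse_genes))
                    human_w = np.ones(len(prof.human_ids))

                reads = _sample_reads(
                    prof, config, lib,
                    {"mouse": m_m, "human": m_h, "spike": m_spike},
                    human_prop, mouse_w, human_w, rng_reads,
                )
                align_frames.append((sample_id, reads))

                length, width = _caliper_from_volume(vol)
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "mouse_id": mouse_id,
                        "humanized": arm.humanized,
                        "xenografted": arm.xenografted,
                        "treatment": arm.treatment,
                        "timepoint": tp.label,
                        "day": day,
                        "plasma_volume_ml": config.plasma_volume_ml,
                        "tumor_length_mm": length,
                        "tumor_width_mm": width,
                    }
                )
                total_mass = m_m + m_h + m_spike
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "mouse_id": mouse_id,
                        "true_volume_mm3": vol,
                        "true_human_pg": m_h,
                        "true_mouse_pg": m_m,
                        "true_spike_pg": m_spike,
                        "true_human_fraction": m_h / (m_h + m_m),
                        "library_size": lib,
                        "expected_human_reads": lib * m_h / total_mass,
                        "expected_mouse_reads": lib * m_m / total_mass,
                        "immune_controlled": immune_controlled,
                        "resistant": resistant,
                    }
                )
                frac_rows.append({"sample_id": sample_id, **tf})

    alignments = _assemble_alignments(align_frames)
    truth = SimTruth(
        samples=pd.DataFrame(truth_rows),
        cell_fractions=pd.DataFrame(frac_rows).set_index("sample_id")
        if frac_rows
        else pd.DataFrame(columns=list(CELL_TYPES)),
        hotspots=prof.hotspots,
        signature_multipliers=prof.signature_multipliers,
    )
    genes = prof.genes.copy()
    spike_rows = pd.DataFrame(
        {
            "gene_id": [s.spike_id for s in config.spikes],
            "species": "spike",
            "contig": [s.spike_id for s in config.spikes],
            "start": 0,
            "end": SPIKE_CONTIG_LEN,
            "biotype": "spike",
        }
    )
    genes = pd.concat([genes, spike_rows], ignore_index=True)
    return Cohort(
        alignments=alignments,
        meta=pd.DataFrame(meta_rows),
        truth=truth,
        genes=genes,
        config=config,
    )


def simulate_controls(
    config: SimConfig,
    n_per_species: int = 3,
    library_size: float = 500_000.0,
    seed_offset: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pure-species control plasma samples for empirical mask derivation.

    Uses the same expression profiles and hotspot pairs as the cohort with the
    same ``config.seed`` (profiles are drawn from the design stream first, so
    they are identical). Human controls express both immune and tumor gene
    classes; no spikes are added.

    Returns (alignment table, control metadata with a ``species`` column).
    """
    ss = np.random.SeedSequence(config.seed)
    s_design, _ = ss.spawn(2)
    prof = _Profiles(config, np.random.default_rng(s_design))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + seed_offset))

    phi = config.expression.dispersion
    gshape = 1.0 / phi if phi > 0 else None
    human_prop = 0.8 * prof.immune_profile(BASE_IMMUNE_FRACTIONS)
    tum_uniform = np.zeros(len(prof.human_ids))
    tum_uniform[: prof.n_tumor] = 1.0 / prof.n_tumor
    human_prop = human_prop + 0.2 * tum_uniform

    frames, meta = [], []
    no_spike = replace(config, spikes=())
    for species in ("mouse", "human"):
        for i in range(n_per_species):
            sid = f"control_{species}_{i + 1}"
            if gshape is not None:
                mw = rng.gamma(gshape, phi, size=len(prof.mouse_genes))
                hw = rng.gamma(gshape, phi, size=len(prof.human_ids))
            else:
                mw = np.ones(len(prof.mouse_genes))
                hw = np.ones(len(prof.human_ids))
            mass = {"mouse": 1.0 if species == "mouse" else 0.0,
                    "human": 1.0 if species == "human" else 0.0}
            reads = _sample_reads(
                prof, no_spike, library_size, mass,
                human_prop, mw, hw, rng,
            )
            frames.append((sid, reads))
            meta.append({"sample_id": sid, "species": species})
    return _assemble_alignments(frames), pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# fixture I/O (plain TSV/BED; round-trips through the readers below)

_FIXTURE_FILES = {
    "alignments": "alignments.tsv",
    "meta": "sample_meta.tsv",
    "genes": "gene_annotation.tsv",
    "truth_samples": "truth_samples.tsv",
    "truth_cell_fractions": "truth_cell_fractions.tsv",
}


def write_fixture(cohort: Cohort, directory: str | os.PathLike) -> None:
    """Write a cohort to TSV tables plus a hotspot ground-truth BED."""
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    try:
        cohort.alignments.to_csv(
            os.path.join(directory, _FIXTURE_FILES["alignments"]), sep="\t", index=False
        )
        cohort.meta.to_csv(
            os.path.join(directory, _FIXTURE_FILES["meta"]), sep="\t", index=False
        )
        cohort.genes.to_csv(
            os.path.join(directory, _FIXTURE_FILES["genes"]), sep="\t", index=False
        )
        cohort.truth.samples.to_csv(
            os.path.join(directory, _FIXTURE_FILES["truth_samples"]), sep="\t", index=False
        )
        cohort.truth.cell_fractions.to_csv(
            os.path.join(directory, _FIXTURE_FILES["truth_cell_fractions"]), sep="\t"
        )
        hs = cohort.truth.hotspots
        with open(os.path.join(directory, "hotspots.bed"), "w") as fh:
            for _, r in hs.iterrows():
                fh.write(f"{r.mouse_contig}\t{r.mouse_start}\t{r.mouse_end}\tpair{r.pair}_mouse\n")
                fh.write(f"{r.human_contig}\t{r.human_start}\t{r.human_end}\tpair{r.pair}_human\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc


def read_fixture(directory: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read back the TSV tables written by :func:`write_fixture`."""
    directory = str(directory)
    out = {}
    for key, fname in _FIXTURE_FILES.items():
        path = os.path.join(directory, fname)
        index_col = 0 if key == "truth_cell_fractions" else None
        try:
            out[key] = pd.read_csv(path, sep="\t", index_col=index_col)
        except OSError as exc:
            raise OSError(f"failed reading {path}: {exc}") from exc
    return out
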