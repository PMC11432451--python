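"""End-to-end orchestration: simulate → mask → split → quantify → statistics.

`run_all` executes the stages in dependency order on a simulated cohort,
writes every result as TSV under an output directory together with a manifest
of parameters and seeds, and is byte-deterministic under a fixed config.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import celldeconv, diffabund, quant, repertoire, signature, simdata, xenosplit

__all__ = ["RunConfig", "run_all", "STAGES"]

STAGES = (
    "simulate",
    "mask",
    "split",
    "quantify",
    "da",
    "impulse",
    "gsea",
    "signature",
    "overlap",
    "deconv",
)

_DEPS = {
    "mask": ("simulate",),
    "split": ("simulate", "mask"),
    "quantify": ("split",),
    "da": ("split",),
    "impulse": ("split",),
    "gsea": ("da",),
    "signature": ("split",),
    "overlap": ("split",),
    "deconv": ("split",),
}

LATE_TIMEPOINTS = ("post_treatment", "sacrifice")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; serializable to/from YAML."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # cohort scale (demo-sized; the generator's own defaults are larger)
    n_mice_per_arm: int = 2
    library_size_mean: float = 50_000.0
    library_size_cv: float = 0.3
    # controls for the empirical mask
    n_controls_per_species: int = 3
    control_library_size: float = 300_000.0
    mask_pad: int = 0
    # thresholds
    q_cutoff: float = 0.05
    min_count: int = 1
    min_mean: float = 1.0
    impulse_min_mean: float = 5.0
    split_fraction: float = 0.7
    n_perm: int = 999
    gsea_n_perm: int = 1000
    nu_grid: tuple[float, ...] = celldeconv.DEFAULT_NU_GRID
    anchor_spike: str = "ERCC-00130"
    deconv_min_human_reads: int = 200
    write_alignments: bool = False

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for st in self.stages:
            missing = [d for d in _DEPS.get(st, ()) if d not in self.stages]
            if missing:
                raise ValueError(f"stage {st!r} requires disabled stages {missing}")

    def sim_config(self) -> simdata.SimConfig:
        return simdata.default_config(
            n_mice_per_arm=self.n_mice_per_arm,
            expression=replace(
                simdata.ExpressionParams(),
                library_size_mean=self.library_size_mean,
                library_size_cv=self.library_size_cv,
            ),
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "nu_grid" in raw:
            raw["nu_grid"] = tuple(raw["nu_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["nu_grid"] = list(d["nu_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _write(df: pd.DataFrame, out_dir: str, name: str, index: bool = False) -> None:
    df.to_csv(os.path.join(out_dir, name), sep="\t", index=index)


def _tumor_volumes(meta: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [quant.tumor_volume(l, w) for l, w in zip(meta.tumor_length_mm, meta.tumor_width_mm)],
        index=meta.sample_id,
        name="tumor_volume_mm3",
    )


def run_all(config: RunConfig, out_dir) -> dict:
    """Run the enabled stages in order, writing TSV outputs and a manifest.

    Returns a dict of in-memory stage results. A stage failure aborts with the
    failing stage named; outputs of completed stages are retained on disk.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    state: dict = {}
    manifest = {"seed": config.seed, "stages_run": [], "parameters": asdict(config)}
    manifest["parameters"]["stages"] = list(config.stages)
    manifest["parameters"]["nu_grid"] = list(config.nu_grid)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, state, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages_run"].append(stage)

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return state


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, state: dict, out_dir: str) -> None:
    simcfg = config.sim_config()
    cohort = simdata.simulate_cohort(simcfg)
    controls, control_meta = simdata.simulate_controls(
        simcfg,
        n_per_species=config.n_controls_per_species,
        library_size=config.control_library_size,
    )
    state.update(cohort=cohort, controls=controls, control_meta=control_meta)
    _write(cohort.meta, out_dir, "sample_meta.tsv")
    _write(cohort.genes, out_dir, "gene_annotation.tsv")
    _write(cohort.truth.samples, out_dir, "truth_samples.tsv")
    cohort.truth.cell_fractions.to_csv(
        os.path.join(out_dir, "truth_cell_fractions.tsv"), sep="\t"
    )
    _write(control_meta, out_dir, "control_meta.tsv")
    if config.write_alignments:
        _write(cohort.alignments, out_dir, "alignments.tsv")


def _stage_mask(config: RunConfig, state: dict, out_dir: str) -> None:
    mask = xenosplit.derive_mask(
        state["controls"],
        state["control_meta"].set_index("sample_id")["species"],
        pad=config.mask_pad,
    )
    mask.to_bed(os.path.join(out_dir, "crossmap_mask.bed"))
    state["mask"] = mask


def _stage_split(config: RunConfig, state: dict, out_dir: str) -> None:
    cohort = state["cohort"]
    kept = xenosplit.apply_mask(xenosplit.select_unique(cohort.alignments), state["mask"])
    counts = xenosplit.count_by_gene(kept, cohort.genes)
    totals = xenosplit.count_species_totals(kept)
    state.update(kept=kept, counts=counts, totals=totals)
    _write(counts, out_dir, "gene_counts.tsv", index=True)
    _write(totals, out_dir, "species_totals.tsv", index=True)


def _species(state: dict) -> pd.Series:
    cohort = state["cohort"]
    return cohort.genes.set_index("gene_id")["species"]


def _stage_quantify(config: RunConfig, state: dict, out_dir: str) -> None:
    cohort, totals = state["cohort"], state["totals"]
    spike = next(
        s for s in cohort.config.spikes if s.spike_id == config.anchor_spike
    )
    meta = cohort.meta.set_index("sample_id")
    species = _species(state)
    counts = state["counts"]
    rows = []
    for sid in meta.index:
        t = totals.loc[sid] if sid in totals.index else None
        row = {"sample_id": sid}
        if t is None or t.get(config.anchor_spike, 0) == 0:
            row.update(human_conc_pg_per_ml=np.nan, mouse_conc_pg_per_ml=np.nan,
                       flagged_no_spike=True)
        else:
            vol = meta.loc[sid, "plasma_volume_ml"]
            row["human_conc_pg_per_ml"] = quant.cfrna_concentration(
                t["human"], t[config.anchor_spike], spike.mass_pg, vol
            )
            row["mouse_conc_pg_per_ml"] = quant.cfrna_concentration(
                t["mouse"], t[config.anchor_spike], spike.mass_pg, vol
            )
            row["flagged_no_spike"] = False
        endo = (t.get("human", 0) + t.get("mouse", 0)) if t is not None else 0
        row["human_fraction"] = (
            quant.species_fraction(counts, species, sid) if endo > 0 else np.nan
        )
        row["detected_human_genes"] = quant.detected_genes(
            counts, species, sid, "human", config.min_count
        )
        row["detected_mouse_genes"] = quant.detected_genes(
            counts, species, sid, "mouse", config.min_count
        )
        rows.append(row)
    qt = pd.DataFrame(rows).set_index("sample_id")
    vols = _tumor_volumes(cohort.meta)
    qt["tumor_volume_mm3"] = vols
    state["quant"] = qt
    _write(qt, out_dir, "quantification.tsv", index=True)

    # tumor-burden correlations in the arm where the xenograft is the only
    # human source (non-humanized, PBS-treated, xenografted mice)
    m = cohort.meta
    sel = m.loc[~m.humanized & m.xenografted & (m.treatment == "PBS"), "sample_id"]
    corr_rows = []
    sub = qt.loc[qt.index.isin(sel)].dropna(subset=["human_conc_pg_per_ml"])
    if len(sub) >= 3:
        for metric in ("human_conc_pg_per_ml", "human_fraction", "detected_human_genes"):
            vals = sub[metric].astype(float)
            if vals.notna().all() and np.ptp(vals) > 0 and np.ptp(sub.tumor_volume_mm3) > 0:
                r, p = quant.spearman(sub.tumor_volume_mm3, vals)
                corr_rows.append({"metric": metric, "spearman_r": r, "pvalue": p,
                                  "n": len(sub)})
    corr = pd.DataFrame(corr_rows, columns=["metric", "spearman_r", "pvalue", "n"])
    state["correlations"] = corr
    _write(corr, out_dir, "burden_correlations.tsv")


def _late_pdtx_labels(state: dict) -> pd.Series:
    """1 = tumor-bearing PBS, 0 = successfully treated, at late draws.

    Immune-controlled PBS mice (no tumor to detect) and treatment-resistant
    mice (tumor never cleared) are excluded via the simulation truth.
    """
    cohort = state["cohort"]
    m = cohort.meta.set_index("sample_id")
    truth = cohort.truth.samples.set_index("sample_id")
    sel = m.xenografted & m.timepoint.isin(LATE_TIMEPOINTS)
    sub = m.loc[sel]
    is_pbs = sub["treatment"] == "PBS"
    keep = (is_pbs & ~truth.loc[sub.index, "immune_controlled"]) | (
        ~is_pbs & ~truth.loc[sub.index, "resistant"]
    )
    return is_pbs.loc[keep].astype(int)


def _stage_da(config: RunConfig, state: dict, out_dir: str) -> None:
    cohort, counts = state["cohort"], state["counts"]
    species = _species(state)
    labels = _late_pdtx_labels(state)
    cols = [c for c in counts.columns if c in labels.index]
    sub = counts[cols]
    grp = np.where(labels.loc[cols] == 1, "PBS", "treated")
    endo = sub.loc[species.reindex(sub.index).isin(["human", "mouse"])]
    sf = diffabund.size_factors(endo)
    dag = diffabund.nb_wald_test(
        endo, grp, sf=sf, min_mean=config.min_mean,
        species=species.reindex(endo.index), reference="treated",
    )
    dag.insert(0, "gene", dag.index)
    state["dag"] = dag
    state["da_samples"] = cols
    _write(dag, out_dir, "differential_abundance.tsv")


def _stage_impulse(config: RunConfig, state: dict, out_dir: str) -> None:
    cohort, counts = state["cohort"], state["counts"]
    species = _species(state)
    m = cohort.meta
    sel = m.loc[~m.humanized & m.xenografted & (m.treatment == "PBS")]
    cols = [c for c in counts.columns if c in set(sel.sample_id)]
    days = sel.set_index("sample_id").loc[cols, "day"].to_numpy(dtype=float)
    human = counts.loc[species.reindex(counts.index) == "human", cols]
    endo = counts.loc[species.reindex(counts.index).isin(["human", "mouse"]), cols]
    sf = diffabund.size_factors(endo)
    res = diffabund.impulse_screen(
        human, days, sf=sf, dispersion="trend", min_mean=config.impulse_min_mean
    )
    res.insert(0, "gene", res.index)
    state["impulse"] = res
    _write(res, out_dir, "impulse_timecourse.tsv")


def _stage_gsea(config: RunConfig, state: dict, out_dir: str) -> None:
    dag = state["dag"]
    human = dag[(dag.get("species") == "human") & dag.log2FC.notna()]
    ranking = human.set_index("gene")["log2FC"]
    res = diffabund.preranked_es(
        ranking, simdata.SIGNATURE_GENES, weight=1.0,
        n_perm=config.gsea_n_perm, seed=config.seed,
    )
    out = pd.DataFrame(
        [{"gene_set": "tumor_signature", "es": res.es, "nes": res.nes,
          "pvalue": res.pvalue, "n_hits": res.n_hits, "n_perm": res.n_perm}]
    )
    state["gsea"] = out
    _write(out, out_dir, "gsea.tsv")


def _stage_signature(config: RunConfig, state: dict, out_dir: str) -> None:
    cohort, counts = state["cohort"], state["counts"]
    species = _species(state)
    # CPM over the whole endogenous library: tumor clearance must show up as
    # a drop in signature abundance relative to total cfRNA, which per-species
    # normalization would erase
    endo = counts.loc[species.reindex(counts.index).isin(["human", "mouse"])]
    cpm = quant.cpm_normalize(endo.loc[:, endo.sum(axis=0) > 0])
    labels = _late_pdtx_labels(state)
    cols = [c for c in cpm.columns if c in labels.index]
    scores = signature.signature_score(cpm[cols], simdata.SIGNATURE_GENES)
    y = labels.loc[cols]
    model, held_out = signature.train_logistic(
        scores, y, split_fraction=config.split_fraction, seed=config.seed
    )
    roc, auc = signature.roc_auc(held_out.p_positive, held_out.label)
    summary = pd.DataFrame(
        [{"auc": auc, "n_train": len(model.training_samples),
          "n_test": len(held_out), "coefficient": model.coefficient,
          "intercept": model.intercept,
          "perfectly_separated": model.perfectly_separated}]
    )
    state.update(signature_scores=scores, signature_model=model,
                 signature_auc=auc, roc=roc)
    _write(scores.rename_axis("sample_id").reset_index(), out_dir, "signature_scores.tsv")
    _write(held_out.rename_axis("sample_id").reset_index(), out_dir, "signature_heldout.tsv")
    _write(roc, out_dir, "roc_points.tsv")
    _write(summary, out_dir, "signature_summary.tsv")


def _stage_overlap(config: RunConfig, state: dict, out_dir: str) -> None:
    cohort, counts = state["cohort"], state["counts"]
    species = _species(state)
    m = cohort.meta
    summary_rows, pair_rows = [], []
    groups = m.loc[m.xenografted].groupby(["humanized", "treatment"])
    for (hum, treat), g in groups:
        if treat != "PBS":
            continue
        gname = ("HIS" if hum else "nonHIS") + "-PDTX-" + treat
        sac = g[g.timepoint == "sacrifice"]
        sets = {
            r.mouse_id: repertoire.detection_set(
                counts, species, r.sample_id, "human", config.min_count
            )
            for r in sac.itertuples()
            if r.sample_id in counts.columns
        }
        sets = {k: v for k, v in sets.items() if v}
        if len(sets) >= 2:
            summ = repertoire.shared_gene_summary(sets)
            summary_rows.append(
                {"group": gname, "n_mice": len(sets),
                 "n_union_genes": int(summ["at_least_k"][1]),
                 "n_shared_by_2plus": int(summ["at_least_k"].get(2, 0)),
                 "fraction_shared_by_2plus": summ["fraction_shared_by_2plus"],
                 "n_shared_by_all": int(summ["at_least_k"].iloc[-1])}
            )
        # matched early/late overlap per mouse
        universe = set().union(*sets.values()) if sets else set()
        early = g[g.timepoint == "pre_treatment"].set_index("mouse_id")
        for mouse, late_set in sets.items():
            if mouse not in early.index:
                continue
            esid = early.loc[mouse, "sample_id"]
            if esid not in counts.columns:
                continue
            eset = repertoire.detection_set(counts, species, esid, "human", config.min_count)
            universe_pair = universe | eset
            if not eset or not late_set:
                continue
            ji = repertoire.jaccard(eset, late_set)
            p = repertoire.jaccard_permutation_p(
                eset, late_set, universe_pair, n_perm=config.n_perm, seed=config.seed
            )
            pair_rows.append({"group": gname, "mouse_id": mouse, "jaccard": ji,
                              "pvalue": p, "n_early": len(eset), "n_late": len(late_set)})
    summary = pd.DataFrame(summary_rows)
    pairs = pd.DataFrame(pair_rows)
    state.update(overlap_summary=summary, overlap_pairs=pairs)
    _write(summary, out_dir, "repertoire_summary.tsv")
    _write(pairs, out_dir, "repertoire_jaccard.tsv")


def _stage_deconv(config: RunConfig, state: dict, out_dir: str) -> None:
    cohort, counts = state["cohort"], state["counts"]
    species = _species(state)
    basis = celldeconv.synthetic_basis(
        n_genes=cohort.config.expression.n_human_immune_genes,
        n_markers_per_type=max(
            1, cohort.config.expression.n_human_immune_genes // (2 * len(celldeconv.CELL_TYPES))
        ),
    )
    human = counts.loc[species.reindex(counts.index) == "human"]
    deep = human.columns[human.sum(axis=0) >= config.deconv_min_human_reads]
    cpm = quant.cpm_normalize(human[deep]) if len(deep) else pd.DataFrame(index=human.index)
    results = {}
    for sid in cpm.columns:
        try:
            results[sid] = celldeconv.nusvr_deconvolve(
                cpm[sid], basis, nu_grid=config.nu_grid, seed=config.seed
            )
        except (ValueError, RuntimeError):
            continue
    meta = cohort.meta.set_index("sample_id")
    frac_rows = []
    for sid, res in results.items():
        for ct, f in res.fractions.items():
            frac_rows.append({"sample_id": sid, "cell_type": ct, "fraction": f,
                              "nu": res.nu, "pearson_r": res.pearson_r})
    fractions = pd.DataFrame(frac_rows)
    if results:
        grouping = meta.loc[list(results)].assign(
            group=lambda d: np.where(d.humanized, "HIS", "nonHIS")
            + np.where(d.xenografted, "-PDTX-", "-nonPDTX-")
            + d.treatment
        )[["group", "timepoint"]]
        traj = celldeconv.deconv_trajectory(results, grouping)
    else:
        traj = pd.DataFrame(columns=["group", "timepoint", "cell_type",
                                     "mean_fraction", "sd_fraction", "n"])
    state.update(deconv_results=results, deconv_trajectory=traj)
    _write(fractions, out_dir, "deconv_fractions.tsv")
    _write(traj, out_dir, "deconv_trajectory.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "mask": _stage_mask,
    "split": _stage_split,
    "quantify": _stage_quantify,
    "da": _stage_da,
    "impulse": _stage_impulse,
    "gsea": _stage_gsea,
    "signature": _stage_signature,
    "overlap": _stage_overlap,
    "deconv": _stage_deconv,
}
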