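"""End-to-end orchestration of the raw and phylogenetically controlled runs.

One config drives: resampling -> GPA over all specimens -> PCA on the
known-class specimens (ordinary, or phylogenetic when enabled) -> CVA on
the retained scores -> Monte Carlo and bootstrap phi nulls ->
resubstitution and jackknife confusion matrices -> projection of the
unknown specimens -> five-point shape models with strobe plots -> the
phylogenetic-signal suite (mass-residual K and lambda, independent
contrasts against body mass).  The two pipeline variants share every
stage implementation; the ordination call is the single point of
divergence.

All outputs are plain text (CSV / JSON / block-text coordinates / SVG)
with fixed 12-significant-digit float formatting, and every random
stream derives from the single configured seed, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .discriminant import (
    GroupedScores, classify, cva_fit, jackknife, null_bootstrap,
    null_montecarlo, project_unknowns,
)
from .ordination import pca_fit, pca_project, phylo_pca_fit
from .outline import resample
from .phylo import contrast_correlation, independent_contrasts, mass_residuals, signal_suite
from .procrustes import gpa
from .shape_models import model_cv_axis, model_pc_axis, strobe_plot
from .trees import prune_to

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    coordinates_path: str
    traits_path: str
    tree_path: str | None = None
    dialect: str = "block-text"
    p: int = 100
    gpa_tolerance: float = 1e-4
    k: int = 3
    replicates: int = 1000
    seed: int = 0
    phylo: bool = False
    write_plots: bool = True
    out_dir: str | None = None

    def validate(self) -> None:
        if self.phylo and self.tree_path is None:
            raise ValueError("phylogenetic mode requested but no tree supplied")
        if self.k < 1:
            raise ValueError("retain at least 1 axis")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.p < 3:
            raise ValueError("p must be >= 3")


def _fmt(value):
    if isinstance(value, float):
        return float(f"{value:.12g}")
    return value


def run_study(
    coordinates: sio.CoordinateDataset,
    traits: pd.DataFrame,
    tree=None,
    p: int = 100,
    gpa_tolerance: float = 1e-4,
    k: int = 3,
    replicates: int = 1000,
    seed: int = 0,
    phylo: bool = False,
    out_dir: str | Path | None = None,
    write_plots: bool = True,
) -> dict:
    """Run the full analysis on in-memory inputs; returns the summary dict.

    When ``out_dir`` is given, scores, assignments, aligned coordinates,
    the consensus, shape-model plots, and the summary JSON are written
    there.
    """
    if phylo and tree is None:
        raise ValueError("phylogenetic mode requested but no tree supplied")
    if tree is not None:
        coordinates, traits, tree, report = sio.reconcile(coordinates, traits, tree)
    else:
        coordinates, traits, _, report = sio.reconcile(coordinates, traits, None)

    resampled = [
        resample(s.points, p=p, species_id=s.species_id) for s in coordinates
    ]
    aligned = gpa(resampled, tolerance=gpa_tolerance)

    classes = traits["feeding_class"]
    known_ids = [i for i in aligned.ids if classes[i] in sio.KNOWN_CLASSES]
    unknown_ids = [i for i in aligned.ids if classes[i] not in sio.KNOWN_CLASSES]
    if len(known_ids) < 4:
        raise ValueError("need at least 4 known-class specimens")
    known = aligned.subset(known_ids)

    if phylo:
        known_tree = prune_to(tree, known_ids)
        pca = phylo_pca_fit(known, known_tree, k=k)
    else:
        pca = pca_fit(known, k=k)

    labels = classes.loc[known_ids].to_numpy()
    grouped = GroupedScores(ids=known_ids, scores=pca.scores[:, :k], labels=labels)
    cva = cva_fit(grouped)
    ss = np.random.SeedSequence(seed)
    mc_seed, boot_seed = (np.random.default_rng(c) for c in ss.spawn(2))
    mc = null_montecarlo(grouped, R=replicates, seed=mc_seed)
    boot = null_bootstrap(grouped, R=replicates, seed=boot_seed)
    assigned, resub = classify(cva, grouped.scores, labels)
    jack = jackknife(grouped)

    unknown_records = []
    if unknown_ids:
        unk = aligned.subset(unknown_ids)
        unknown_records = project_unknowns(cva, pca, unk.configs, ids=unknown_ids)
    unknown_counts = {g: 0 for g in cva.groups}
    for rec in unknown_records:
        unknown_counts[rec["assigned"]] += 1

    pc_series = [model_pc_axis(pca, a) for a in range(min(3, pca.k))]
    cv_series = model_cv_axis(cva, pca)

    signal = {}
    if tree is not None and "body_mass_g" in traits.columns:
        scored_ids = known_ids + unknown_ids
        all_scores = np.vstack(
            [pca.scores[:, :k]]
            + ([pca_project(pca, aligned.subset(unknown_ids).configs)[:, :k]]
               if unknown_ids else [])
        )
        mass = traits.loc[scored_ids, "body_mass_g"].dropna()
        usable = [i for i in scored_ids if i in mass.index]
        if len(usable) >= 4:
            sub_tree = prune_to(tree, usable)
            score_df = pd.DataFrame(
                all_scores[: len(scored_ids), :2],
                index=scored_ids,
                columns=["PC1", "PC2"],
            ).loc[usable]
            log_mass = pd.Series(
                np.log10(mass.loc[usable]), index=usable, name="log10_mass"
            )
            sig_seed = np.random.default_rng(ss.spawn(1)[0])
            mass_ic = independent_contrasts(log_mass, sub_tree)
            for axis in ("PC1", "PC2"):
                resid = mass_residuals(score_df[axis], mass.loc[usable])
                res = signal_suite(
                    resid, sub_tree, name=f"{axis}_mass_residual", seed=sig_seed
                )
                ic = independent_contrasts(score_df[axis], sub_tree)
                rho, p_rho = contrast_correlation(mass_ic, ic, "spearman")
                tau, p_tau = contrast_correlation(mass_ic, ic, "kendall")
                signal[axis] = {
                    "blomberg_K": _fmt(res.K),
                    "p_K": _fmt(res.p_K),
                    "pagel_lambda": _fmt(res.lam),
                    "logL_lambda": _fmt(res.logL_lambda),
                    "p_lambda": _fmt(res.p_lambda),
                    "contrast_spearman_rho": _fmt(rho),
                    "contrast_spearman_p": _fmt(p_rho),
                    "contrast_kendall_tau": _fmt(tau),
                    "contrast_kendall_p": _fmt(p_tau),
                }

    summary = {
        "mode": "phylogenetic" if phylo else "raw",
        "n_species": len(aligned.ids),
        "n_known": len(known_ids),
        "n_unknown": len(unknown_ids),
        "gpa_iterations": aligned.iterations,
        "gpa_final_change": _fmt(aligned.final_change),
        "variance_fraction": [_fmt(v) for v in pca.variance_fraction[:k]],
        "variance_pct_retained": _fmt(100.0 * float(np.sum(pca.variance_fraction[:k]))),
        "wilks_lambda": _fmt(cva.wilks_lambda),
        "phi": _fmt(cva.phi),
        "p_chi2": _fmt(cva.p_chi2),
        "p_mc": _fmt(mc.p_value),
        "p_mc_conservative": _fmt(mc.p_conservative),
        "p_boot": _fmt(boot.p_value),
        "p_boot_conservative": _fmt(boot.p_conservative),
        "pct_correct": _fmt(resub.percent_correct),
        "pct_correct_jackknife": _fmt(jack.percent_correct),
        "confusion_resubstitution": resub.as_dict(),
        "confusion_jackknife": jack.as_dict(),
        "unknown_assignments": unknown_counts,
        "n_unknown_outside_range": sum(
            1 for r in unknown_records if r["outside_observed_range"]
        ),
        "reconcile": {"n_retained": report["n_retained"]},
        "seed": seed,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_coordinates(
            sio.CoordinateDataset(
                [type(resampled[0])(i, c) for i, c in zip(aligned.ids, aligned.configs)]
            ),
            out / "aligned_coordinates.txt",
        )
        sio.write_coordinates(
            sio.CoordinateDataset([type(resampled[0])("consensus", aligned.consensus)]),
            out / "consensus.txt",
        )
        pd.DataFrame(
            pca.scores[:, :k], index=known_ids,
            columns=[f"PC{j + 1}" for j in range(k)],
        ).to_csv(out / "pc_scores.csv", float_format=FLOAT_FMT, index_label="species")
        pd.DataFrame(
            {"cv_score": cva.cv_scores, "feeding_class": labels, "assigned": assigned},
            index=known_ids,
        ).to_csv(out / "cv_scores.csv", float_format=FLOAT_FMT, index_label="species")
        if unknown_records:
            pd.DataFrame(unknown_records).set_index("id").to_csv(
                out / "unknown_assignments.csv", float_format=FLOAT_FMT,
                index_label="species",
            )
        if signal:
            (out / "phylo_signal.json").write_text(
                json.dumps(signal, indent=2, sort_keys=True) + "\n"
            )
        if write_plots:
            models = out / "models"
            models.mkdir(exist_ok=True)
            for series in pc_series + [cv_series]:
                strobe_plot(series, models / f"{series.axis_id}_strobe.svg")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )

    summary["phylo_signal"] = signal
    return summary


def run_all(config: PipelineConfig) -> dict:
    """Read the configured inputs and run the full pipeline."""
    config.validate()
    coords = sio.read_coordinates(config.coordinates_path, dialect=config.dialect)
    traits = sio.read_traits(config.traits_path)
    tree = sio.read_tree(config.tree_path) if config.tree_path else None
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
        )
    return run_study(
        coords, traits, tree,
        p=config.p, gpa_tolerance=config.gpa_tolerance, k=config.k,
        replicates=config.replicates, seed=config.seed, phylo=config.phylo,
        out_dir=out_dir, write_plots=config.write_plots,
    )
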