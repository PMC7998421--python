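"""End-to-end pipeline: simulate -> segment -> characterize -> cata.

Each stage reads and writes the same CSV schemas as the standalone
commands, so a run can mix simulated and user-supplied inputs. A run
archives its effective configuration next to the outputs and logs
seeds, versions, and counts at each stage; rerunning with the same
config reproduces every numeric table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cata import CATACube, cata_report
from .characterize import (
    kruskal_wallis,
    liking_with_never_tasted,
    one_way_anova,
    sdcf_pairwise,
    two_way_anova,
)
from .datamodel import RatingTable, write_report
from .segmentation import segment_ratings, segment_summary
from .synthetic import (
    CohortConfig,
    generate_cata,
    generate_phenol_table,
    generate_ratings,
    generate_traits,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "hedoseg_run"
    seed: int = 0
    k: int = 3
    restarts: int = 50
    alpha: float = 0.05
    n_subjects: int = 1208
    steps: tuple = ("simulate", "segment", "characterize", "cata")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


class MissingInputError(FileNotFoundError):
    """A stage needs output from a stage that was toggled off."""


def _setup_logging(out: Path) -> None:
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("hedoseg").addHandler(handler)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return the report bundle as DataFrames.

    Outputs (CSV) land in ``config.out_dir`` along with the archived
    config (``config.json``) and a run log. Any stage failure raises
    after logging the stage name; partial outputs are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    (out / "config.json").write_text(config.to_json())
    logger.info("hedoseg %s starting run with seed %d", __version__, config.seed)

    bundle: dict = {}
    ratings = truth = traits = profiles = None

    if "simulate" in config.steps:
        cohort = CohortConfig(n_subjects=config.n_subjects, seed=config.seed)
        ratings, truth = generate_ratings(cohort)
        traits, profiles = generate_traits(cohort, truth)
        ratings.records.to_csv(out / "ratings.csv", index=False)
        traits.rename_axis("subject_id").to_csv(out / "traits.csv")
        profiles.to_csv(out / "profiles.csv", index=False)
        truth.phenotypes.rename_axis("subject_id").to_frame().to_csv(out / "ground_truth.csv")
        logger.info(
            "simulated %d subjects (truncation fraction %.4f)",
            cohort.n_subjects,
            truth.truncation_fraction,
        )

    if "segment" in config.steps:
        if ratings is None:
            path = out / "ratings.csv"
            if not path.exists():
                raise MissingInputError(f"segment needs {path}; enable the simulate step")
            ratings = RatingTable(pd.read_csv(path))
        model, vectors = segment_ratings(
            ratings, k=config.k, restarts=config.restarts, seed=config.seed
        )
        n_total = len(ratings.subjects)
        summary = segment_summary(model, n_total=n_total)
        centroids = model.centroids.copy()
        centroids.insert(0, "phenotype", [model.labels[i] for i in centroids.index])
        write_report(centroids.reset_index(), out / "centroids.csv")
        write_report(summary, out / "cluster_summary.csv")
        assign = model.assignments.rename_axis("subject_id").to_frame()
        assign["phenotype"] = assign["cluster"].map(model.labels)
        write_report(assign.reset_index(), out / "assignments.csv")
        write_report(model.exclusions, out / "exclusions.csv")
        logger.warning("%d subjects excluded (zero variance)", len(model.exclusions))
        bundle.update(
            {"centroids": centroids, "cluster_summary": summary, "assignments": assign,
             "exclusions": model.exclusions, "vectors": vectors}
        )

    if "characterize" in config.steps:
        if "assignments" not in bundle:
            raise MissingInputError("characterize needs the segment step's assignments")
        assign = bundle["assignments"]
        merged = ratings.records.merge(assign.reset_index(), on="subject_id", how="inner")
        conc = {s.code: s.sucrose_conc for s in ratings.samples}
        rows = []
        for attr in ("liking", "sweet", "bitter", "astringent", "overall_flavour"):
            sub = merged[merged["attribute"] == attr]
            res = two_way_anova(
                sub["value"],
                sub["phenotype"],
                sub["sample_code"].map(conc),
                alpha=config.alpha,
                names=("cluster", "concentration"),
            )
            for _, t in res.terms.iterrows():
                rows.append(
                    {"attribute": attr, "term": t["name"], "df": t["df"],
                     "F": t["F"], "p": t["p"], "residual_df": res.residual_df}
                )
        anova_table = pd.DataFrame(rows)
        write_report(anova_table, out / "sensory_anova.csv")
        bundle["sensory_anova"] = anova_table

        if traits is None:
            tpath = out / "traits.csv"
            if not tpath.exists():
                raise MissingInputError(f"characterize needs {tpath}")
            traits = pd.read_csv(tpath, index_col="subject_id")
        tmerged = traits.join(assign["phenotype"], how="inner")
        trows = []
        for trait in traits.columns:
            res = one_way_anova(tmerged[trait], tmerged["phenotype"], alpha=config.alpha)
            means = res.ls_means.set_index("level")["mean"]
            trows.append(
                {
                    "trait": trait,
                    **{f"mean_{lvl}": means.get(lvl, np.nan) for lvl in means.index},
                    "F": res.terms["F"].iloc[0],
                    "p": res.terms["p"].iloc[0],
                    "letters": json.dumps(res.letters),
                }
            )
        trait_table = pd.DataFrame(trows)
        write_report(trait_table, out / "trait_characterization.csv")
        bundle["trait_characterization"] = trait_table

    if "cata" in config.steps:
        cohort = CohortConfig(n_subjects=config.n_subjects, seed=config.seed)
        cata_long = generate_cata(cohort)
        cata_long.to_csv(out / "cata.csv", index=False)
        phenol = generate_phenol_table(cohort)
        phenol.rename_axis("product").to_csv(out / "phenol.csv")
        cube = CATACube(cata_long)
        report = cata_report(cube, phenol=phenol, alpha=config.alpha, seed=config.seed)
        write_report(report["screen"], out / "cata_screen.csv")
        coords = report["ca"].row_coordinates_.iloc[:, :2]
        write_report(coords.rename_axis("product").reset_index(), out / "ca_coordinates.csv")
        write_report(
            report["groups"].rename_axis("product").reset_index(), out / "product_groups.csv"
        )
        if "phenol" in report:
            write_report(report["phenol"], out / "phenol_correlation.csv")
        bundle.update({f"cata_{k}": v for k, v in report.items() if k != "ca"})
        bundle["cata_ca"] = report["ca"]

    logger.info("run complete; outputs in %s", out)
    return bundle


__all__ = [
    "PipelineConfig",
    "MissingInputError",
    "run_pipeline",
    "kruskal_wallis",
    "sdcf_pairwise",
    "liking_with_never_tasted",
]
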