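"""End-to-end analysis orchestration.

Reproduces the full analysis layout on either user data or a simulated
sample: per epiphysis (proximal/distal) and cohort (pooled plus each
population) — consensus sliding, GPA, shape and form PCA, PC-CS
correlations, Procrustes ANOVA on sex, centroid-size ANOVA with post hoc
comparisons, allometric trajectory comparisons, and the LOOCV LDA suite on
shape PCs, form PCs, and CS.  All permutation seeds derive from the master
seed through a counter, so results are a pure function of (inputs, config,
seed) and adding an analysis never perturbs existing numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import classify_by_cs, select_pcs
from .inference import (
    anova_cs,
    compare_trajectories,
    correlate_pc_cs,
    procrustes_anova_rrpp,
)
from .io import (
    Sample,
    assemble_sample,
    load_fibula_template,
    read_landmark_file,
    read_metadata,
    read_template,
    split_by_region,
)
from .ordination import form_pca, shape_pca
from .procrustes import gpa_align
from .simulate import default_params, simulate_sample
from .sliding import slide_sample

logger = logging.getLogger(__name__)

MIN_COHORT_PER_SEX = 3


@dataclass
class AnalysisConfig:
    coordinates: str | None = None  # TPS or delimited coordinate file
    metadata: str | None = None
    template: str | None = None  # defaults to the packaged fibula template
    simulate_preset: str | None = None  # alternative to file input
    sliding_iterations: int = 3
    sliding_k_neighbors: int = 8
    n_permutations: int = 1000
    lda_max_pcs: int = 10
    lda_variance_threshold: float = 0.70
    seed: int = 1
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be at least 99")
        has_files = self.coordinates is not None and self.metadata is not None
        if not has_files and self.simulate_preset is None:
            raise ValueError("provide coordinate+metadata files or a simulate preset")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        payload = {
            "provenance": self.provenance,
            "tables": {
                name: t.to_dict(orient="records") for name, t in self.tables.items()
            },
        }
        (out / "bundle.json").write_text(json.dumps(payload, indent=2, default=str))

    @staticmethod
    def read(output_dir: str | Path) -> "ReportBundle":
        payload = json.loads((Path(output_dir) / "bundle.json").read_text())
        return ReportBundle(
            tables={
                name: pd.DataFrame(rows) for name, rows in payload["tables"].items()
            },
            provenance=payload["provenance"],
        )


class _SeedSequencer:
    """Deterministic per-test seeds derived from the master seed."""

    def __init__(self, master: int):
        self.master = master
        self.counter = 0

    def next(self) -> int:
        self.counter += 1
        ss = np.random.SeedSequence([self.master, self.counter])
        return int(ss.generate_state(1)[0] % (2**31))


def _load_sample(config: AnalysisConfig) -> Sample:
    if config.simulate_preset is not None:
        params = default_params(seed=config.seed, preset=config.simulate_preset)
        sample, _ = simulate_sample(params)
        return sample
    template = (
        read_template(config.template) if config.template else load_fibula_template()
    )
    configs = read_landmark_file(config.coordinates, template)
    metadata = read_metadata(config.metadata)
    return assemble_sample(configs, metadata, template)


def _cohorts(sample: Sample) -> dict[str, Sample]:
    cohorts: dict[str, Sample] = {"pooled": sample}
    for pop in sorted(set(sample.labels_for("population"))):
        ids = [
            sid
            for sid in sample.specimen_ids
            if sample.metadata[sid].population == pop
        ]
        cohorts[pop] = sample.subset(ids)
    return cohorts


def _sex_cells_ok(cohort: Sample) -> bool:
    sexes = cohort.labels_for("sex")
    return all(np.sum(sexes == s) >= MIN_COHORT_PER_SEX for s in ("M", "F"))


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full pipeline and return (optionally write) the report bundle."""
    seeds = _SeedSequencer(config.seed)
    sample = _load_sample(config)
    proximal, distal = split_by_region(sample)

    bundle = ReportBundle(
        provenance={
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "fibmorph_version": __version__,
            "n_specimens": len(sample),
        }
    )

    pca_rows, corr_rows, shape_anova_rows = [], [], []
    cs_anova_rows, posthoc_rows, cs_box_rows = [], [], []
    trajectory_rows, lda_rows = [], []

    for region_name, region_sample in (("proximal", proximal), ("distal", distal)):
        slid, sliding_report = slide_sample(
            region_sample,
            outer_iterations=config.sliding_iterations,
            k_neighbors=config.sliding_k_neighbors,
        )
        logger.info(
            "%s: sliding ran %d iterations (max displacement %.4g mm)",
            region_name,
            sliding_report.iterations_run,
            sliding_report.max_displacement_mm,
        )
        gpa = gpa_align([c.coords for c in slid.configurations])
        shape_model = shape_pca(gpa)
        form_model = form_pca(gpa)
        cs = gpa.centroid_sizes
        sex = slid.labels_for("sex")
        population = slid.labels_for("population")

        for model in (shape_model, form_model):
            for j in range(min(5, model.n_components)):
                pca_rows.append(
                    {
                        "epiphysis": region_name,
                        "space": model.space,
                        "pc": j + 1,
                        "variance_pct": 100 * model.variance_fraction[j],
                        "seed": config.seed,
                    }
                )

        for res in correlate_pc_cs(shape_model, cs, [0, 1]):
            corr_rows.append(
                {
                    "epiphysis": region_name,
                    "cohort": "pooled",
                    "pc": res.pc_index + 1,
                    "r": res.r,
                    "p": res.p,
                    "seed": config.seed,
                }
            )

        cohorts = _cohorts(slid)
        index = {sid: i for i, sid in enumerate(slid.specimen_ids)}
        for cohort_name, cohort in cohorts.items():
            rows = np.array([index[sid] for sid in cohort.specimen_ids])
            cohort_sex = sex[rows]
            if not _sex_cells_ok(cohort):
                logger.warning(
                    "%s/%s: fewer than %d per sex; skipping cohort analyses",
                    region_name,
                    cohort_name,
                    MIN_COHORT_PER_SEX,
                )
                continue

            shape_flat = gpa.aligned[rows].reshape(len(rows), -1)
            res = procrustes_anova_rrpp(
                shape_flat,
                cohort_sex,
                n_perm=config.n_permutations,
                seed=seeds.next(),
                factor="sex",
            )
            shape_anova_rows.append(
                {
                    "epiphysis": region_name,
                    "cohort": cohort_name,
                    "factor": "sex",
                    "F": res.F,
                    "p": res.p,
                    "n": len(rows),
                    "seed": config.seed,
                }
            )

            anova, posthoc, box = anova_cs(cs[rows], cohort_sex, factor="sex")
            cs_anova_rows.append(
                {
                    "epiphysis": region_name,
                    "cohort": cohort_name,
                    "factor": "sex",
                    "F": anova.F,
                    "p": anova.p,
                    "n": len(rows),
                    "seed": config.seed,
                }
            )
            for level, stats_ in box.items():
                cs_box_rows.append(
                    {
                        "epiphysis": region_name,
                        "cohort": cohort_name,
                        "level": level,
                        **{k: v for k, v in stats_.items() if k != "outliers"},
                        "n_outliers": len(stats_["outliers"]),
                        "seed": config.seed,
                    }
                )

            # form PC1 sex ANOVA (the study's headline form statistic)
            form_scores = form_model.scores[rows]
            res_pc1 = procrustes_anova_rrpp(
                form_scores[:, :1],
                cohort_sex,
                n_perm=config.n_permutations,
                seed=seeds.next(),
                factor="sex",
            )
            shape_anova_rows.append(
                {
                    "epiphysis": region_name,
                    "cohort": cohort_name,
                    "factor": "sex-on-form-PC1",
                    "F": res_pc1.F,
                    "p": res_pc1.p,
                    "n": len(rows),
                    "seed": config.seed,
                }
            )

            # LDA suite
            for space_name, model in (("shape", shape_model), ("form", form_model)):
                k, report = select_pcs(
                    type(model)(
                        space=model.space,
                        mean_vector=model.mean_vector,
                        axes=model.axes,
                        eigenvalues=model.eigenvalues,
                        scores=model.scores[rows],
                        variance_fraction=model.variance_fraction,
                    ),
                    cohort_sex,
                    max_pcs=config.lda_max_pcs,
                    variance_threshold=config.lda_variance_threshold,
                )
                lda_rows.append(
                    {
                        "epiphysis": region_name,
                        "cohort": cohort_name,
                        "feature_set": f"{space_name}-PCs",
                        "n_pcs": k,
                        "cumulative_variance_pct": 100 * report.cumulative_variance,
                        "n_correct": report.n_correct,
                        "n_total": report.n_total,
                        "accuracy_pct": round(report.accuracy_pct),
                        "seed": config.seed,
                    }
                )
            cs_report = classify_by_cs(cs[rows], cohort_sex)
            lda_rows.append(
                {
                    "epiphysis": region_name,
                    "cohort": cohort_name,
                    "feature_set": "CS",
                    "n_pcs": 0,
                    "cumulative_variance_pct": float("nan"),
                    "n_correct": cs_report.n_correct,
                    "n_total": cs_report.n_total,
                    "accuracy_pct": round(cs_report.accuracy_pct),
                    "seed": config.seed,
                }
            )

        # population-level CS ANOVA + post hoc on the pooled sample
        pops = sorted(set(population))
        if len(pops) >= 2:
            anova_pop, posthoc_pop, _ = anova_cs(cs, population, factor="population")
            cs_anova_rows.append(
                {
                    "epiphysis": region_name,
                    "cohort": "pooled",
                    "factor": "population",
                    "F": anova_pop.F,
                    "p": anova_pop.p,
                    "n": len(cs),
                    "seed": config.seed,
                }
            )
            posthoc_pop.insert(0, "epiphysis", region_name)
            posthoc_rows.append(posthoc_pop)

        # allometric trajectories: population pairs (pooled), sexes per population
        for space_name, model in (("shape", shape_model), ("form", form_model)):
            for i, a in enumerate(pops):
                for b in pops[i + 1 :]:
                    if min(np.sum(population == a), np.sum(population == b)) < 3:
                        continue
                    comp = compare_trajectories(
                        model.scores,
                        cs,
                        population,
                        a,
                        b,
                        n_perm=config.n_permutations,
                        seed=seeds.next(),
                    )
                    trajectory_rows.append(
                        {
                            "epiphysis": region_name,
                            "space": space_name,
                            "cohort": "pooled",
                            "pair": f"{a}-{b}",
                            "angle_deg": comp.angle_deg,
                            "p_angle": comp.p_angle,
                            "length_difference": comp.length_difference,
                            "p_length": comp.p_length,
                            "seed": config.seed,
                        }
                    )
            for cohort_name, cohort in cohorts.items():
                if cohort_name == "pooled" or not _sex_cells_ok(cohort):
                    continue
                rows = np.array([index[sid] for sid in cohort.specimen_ids])
                comp = compare_trajectories(
                    model.scores[rows],
                    cs[rows],
                    sex[rows],
                    "M",
                    "F",
                    n_perm=config.n_permutations,
                    seed=seeds.next(),
                )
                trajectory_rows.append(
                    {
                        "epiphysis": region_name,
                        "space": space_name,
                        "cohort": cohort_name,
                        "pair": "M-F",
                        "angle_deg": comp.angle_deg,
                        "p_angle": comp.p_angle,
                        "length_difference": comp.length_difference,
                        "p_length": comp.p_length,
                        "seed": config.seed,
                    }
                )

    bundle.tables["pca_variance"] = pd.DataFrame(pca_rows)
    bundle.tables["pc_cs_correlations"] = pd.DataFrame(corr_rows)
    bundle.tables["procrustes_anova"] = pd.DataFrame(shape_anova_rows)
    bundle.tables["cs_anova"] = pd.DataFrame(cs_anova_rows)
    if posthoc_rows:
        bundle.tables["cs_posthoc"] = pd.concat(posthoc_rows, ignore_index=True)
    bundle.tables["cs_boxplots"] = pd.DataFrame(cs_box_rows)
    bundle.tables["trajectories"] = pd.DataFrame(trajectory_rows)
    bundle.tables["lda"] = pd.DataFrame(lda_rows)

    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
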