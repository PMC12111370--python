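"""End-to-end pipeline driver.

Runs the two-stage analysis on a synthetic (or loaded) cohort: preprocess ->
PCA screening with factor description -> deconvolution of the selected
samples -> secondary-structure class totals -> pairwise comparisons.  Every
report records the seed and a hash of the configuration, so a run is
reproducible from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import compare as cmp_mod
from .deconv import FitConstraints, deconvolve_portions
from .io import read_spectra_dir, read_factor_table, write_factor_table, write_spectrum
from .multivariate import (
    build_matrix,
    describe_dimension,
    kaiser_retain,
    level_distances,
    run_pca,
)
from .preprocess import PreprocessParams, preprocess
from .structure import class_totals
from .synth import SyntheticConfig, generate_cohort

log = logging.getLogger(__name__)

#: Samples selected for deconvolution by default (homogeneous in sex/age,
#: contrasting in caries, periodontal and comorbidity status).
DEFAULT_SELECTION = ("FYHHH", "FOCHH", "FOCMC", "FOMLG")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    input_dir: str | None = None  # measured spectra; None -> synthesize
    factor_table: str | None = None
    output_dir: str = "amide3_run"
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    constraints: FitConstraints = field(default_factory=FitConstraints)
    scale_unit: bool = True
    n_pcs: int = 2
    selection: tuple[str, ...] = DEFAULT_SELECTION
    alpha: float = 0.05
    family: str = "run"
    write_spectra: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full two-stage analysis and write CSV reports.

    Returns the report bundle as a dict of DataFrames; the same tables are
    written under ``config.output_dir``.  A stage failure aborts with the
    stage name; partial outputs are kept on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    log.info("pipeline start: seed=%(seed)s hash=%(config_hash)s", meta)

    stage = "synthesize-or-load"
    try:
        if config.input_dir:
            spectra = read_spectra_dir(config.input_dir)
            factors = (
                read_factor_table(config.factor_table) if config.factor_table else None
            )
        else:
            synth_cfg = SyntheticConfig(
                components=config.synth.components,
                grid=config.synth.grid,
                baseline_coeffs=config.synth.baseline_coeffs,
                noise_sd=config.synth.noise_sd,
                portion_scale_sd=config.synth.portion_scale_sd,
                n_portions=config.synth.n_portions,
                seed=config.seed,
            )
            spectra, factors = generate_cohort(config=synth_cfg)
            write_factor_table(factors, out / "factors.csv")
            if config.write_spectra:
                for s in spectra:
                    write_spectrum(s, out / "spectra" / f"{s.sample_id}_{s.portion_id}.csv")

        stage = "preprocess"
        processed = [preprocess(s, config.preprocess) for s in spectra]

        stage = "pca-screening"
        matrix = build_matrix(processed, band=config.preprocess.band, factors=factors)
        pca = run_pca(matrix, scale_unit=config.scale_unit)
        retained = max(kaiser_retain(pca.eigenvalues, config.scale_unit), config.n_pcs)
        scree = pd.DataFrame(
            {
                "eigenvalue": pca.eigenvalues,
                "explained_pct": pca.explained_pct,
                "cumulative_pct": pca.cumulative_pct,
            },
            index=pca.scores.columns,
        )
        assoc = (
            describe_dimension(pca, matrix.factors, n_pcs=retained)
            if not matrix.factors.empty
            else None
        )
        dist = (
            level_distances(pca, matrix.factors, n_pcs=config.n_pcs)
            if not matrix.factors.empty
            else None
        )

        stage = "deconvolution"
        selection = [s for s in config.selection if s in {str(x.sample_id) for x in spectra}]
        per_sample = {}
        table_rows = []
        totals_rows = []
        for sid in selection:
            portions = [p for p in processed if str(p.sample_id) == sid]
            results = deconvolve_portions(
                portions,
                constraints=config.constraints,
                sg_window=config.preprocess.sg_window,
                sg_order=config.preprocess.sg_order,
            )
            per_sample[sid] = results
            for m in ("area", "relative_pct"):
                summ = cmp_mod.summarize_portions(results, m)
                for comp, st in summ.items():
                    table_rows.append(
                        {"sample": sid, "component": comp, "measure": m,
                         "mean": st.mean, "sd": st.sd, "n": st.n}
                    )
            totals = class_totals(results[0])
            for cls, pct in totals.pct.items():
                totals_rows.append(
                    {"sample": sid, "class": cls,
                     "area_total": totals.area[cls], "pct_total": pct}
                )

        stage = "pairwise-comparison"
        pairs = list(combinations(selection, 2))
        cmp_frames = []
        for a, b in pairs:
            c = cmp_mod.compare_samples(
                per_sample[a], per_sample[b],
                alpha=config.alpha, family=config.family, n_pairs=len(pairs),
            )
            c.insert(0, "pair", f"{a}-{b}")
            cmp_frames.append(c)
        comparisons = (
            pd.concat(cmp_frames, ignore_index=True) if cmp_frames else pd.DataFrame()
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle: dict[str, pd.DataFrame] = {
        "scree": scree,
        "scores": pca.scores,
        "deconvolution": pd.DataFrame(table_rows),
        "class_totals": pd.DataFrame(totals_rows),
        "comparisons": comparisons,
    }
    if assoc is not None:
        bundle["anova"] = assoc.anova
        bundle["levels"] = assoc.levels
    if dist is not None:
        bundle["distances"] = pd.concat(
            {f: s.rename("distance").to_frame() for f, s in dist.to_center.items()},
            names=["factor", "level"],
        ).reset_index()
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=name in ("scree", "scores"))
    log.info("pipeline done: %d reports in %s", len(bundle), out)
    return bundle
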