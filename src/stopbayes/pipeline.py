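"""End-to-end orchestration of the full analysis chain.

cohort generation -> analysis-side p(Stop) estimation -> behavioral
summaries -> first-level GLM with the +-1 contrasts on the GS p(Stop)
modulator -> second-level trait regressions per ROI -> gender
slope comparisons -> plain-text report.  The whole chain is a pure
function of (config, seed): identical inputs give identical outputs.

The analysis-side belief-model parameters may differ from the generating
side (they are recorded separately in the provenance block); with matched
defaults the analysis p(Stop) reproduces the generating trace exactly,
since the model is deterministic in the trial sequence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dbm import DBMParams, run_sequence
from .behavior import summarize
from .glm import HRFSpec, build_design, fit_glm_ar1, contrast, modulator_contrast_weights
from .stats import second_level_regression, compare_slopes, two_sample_t, correlate
from .cohort import CohortConfig, CohortBundle, generate_cohort, write_bundle, _config_to_dict

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_all", "attach_pstop", "first_level_contrasts"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = CohortConfig()
    analysis_dbm: DBMParams = DBMParams()
    hrf: HRFSpec = HRFSpec()
    orthogonalize_modulators: bool = False
    bonferroni: bool = True
    out_dir: str | None = None
    write_bundle_files: bool = False


@dataclass
class RunResult:
    """All tables the pipeline emits, plus provenance."""

    behavioral: pd.DataFrame  # one row per subject
    contrasts: pd.DataFrame  # subject_id, roi, contrast, estimate, t
    second_level: dict  # roi -> RegressionReport
    slope_comparisons: pd.DataFrame
    bundle: CohortBundle
    provenance: dict
    report_text: str = ""


def attach_pstop(events: pd.DataFrame, params: DBMParams) -> pd.DataFrame:
    """Recompute p(Stop) from the trial sequence with analysis-side params."""
    out = events.copy()
    cats = (out["trial_type"] == "stop").astype(int).to_numpy()
    out["pstop"] = run_sequence(cats, params)
    return out


def first_level_contrasts(
    events: pd.DataFrame,
    bold: pd.DataFrame,
    hrf: HRFSpec,
    n_volumes_per_session: int = 300,
    orthogonalize_modulators: bool = False,
) -> pd.DataFrame:
    """Fit the AR(1) GLM per ROI and return the +-1 GS p(Stop) contrasts."""
    X = build_design(
        events,
        hrf,
        n_volumes_per_session,
        orthogonalize_modulators=orthogonalize_modulators,
    )
    rois = [c for c in bold.columns if c != "session"]
    sid = str(events["subject_id"].iat[0])
    rows = []
    for roi in rois:
        fit = fit_glm_ar1(bold[roi].to_numpy(dtype=float), X)
        for sign, name in ((1.0, "GS_pstop>0"), (-1.0, "GS_pstop<0")):
            est, t = contrast(fit, modulator_contrast_weights(X, "GS_pstop", sign))
            rows.append(
                {"subject_id": sid, "roi": roi, "contrast": name, "estimate": est, "t": t, "rho": fit.rho}
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig | None = None, seed: int = 0) -> RunResult:
    """Execute the full chain deterministically and assemble the report."""
    if config is None:
        config = RunConfig()
    t_start = time.time()
    timings = {}

    def stage(name):
        timings[name] = time.time() - t_start
        logger.info("stage %s done at %.1fs", name, timings[name])

    bundle = generate_cohort(config.cohort, seed=seed, include_bold=True)
    stage("cohort")

    # analysis-side p(Stop) + behavioral summaries
    analyzed = {sid: attach_pstop(ev, config.analysis_dbm) for sid, ev in bundle.events.items()}
    behavioral = pd.DataFrame([dataclasses.asdict(summarize(ev)) for ev in analyzed.values()])
    stage("behavior")

    con_rows = [
        first_level_contrasts(
            analyzed[sid],
            bundle.bold[sid],
            config.hrf,
            config.cohort.n_volumes_per_session,
            config.orthogonalize_modulators,
        )
        for sid in analyzed
    ]
    contrasts = pd.concat(con_rows, ignore_index=True)
    stage("first_level")

    pos = contrasts[contrasts["contrast"] == "GS_pstop>0"]
    table = bundle.cohort.merge(
        pos.pivot(index="subject_id", columns="roi", values="estimate").reset_index(),
        on="subject_id",
    )
    second_level = {
        roi: second_level_regression(table, roi) for roi in bundle.config.rois
    }
    stage("second_level")

    slope_rows = []
    trait_of = {roi: spec.trait for roi, spec in bundle.config.rois.items()}
    men = table[table["gender"] == "M"]
    women = table[table["gender"] == "F"]
    for roi, trait in trait_of.items():
        t, dof, p = compare_slopes(men[trait], men[roi], women[trait], women[roi])
        slope_rows.append({"roi": roi, "trait": trait, "t": t, "dof": dof, "p": p})
    slope_comparisons = pd.DataFrame(slope_rows)
    stage("slopes")

    config_dict = {
        "cohort": _config_to_dict(config.cohort),
        "analysis_dbm": dataclasses.asdict(config.analysis_dbm),
        "hrf": dataclasses.asdict(config.hrf),
        "orthogonalize_modulators": config.orthogonalize_modulators,
    }
    provenance = {
        "version": __version__,
        "seed": seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stage_timings_s": {k: round(v, 2) for k, v in timings.items()},
    }

    result = RunResult(
        behavioral=behavioral,
        contrasts=contrasts,
        second_level=second_level,
        slope_comparisons=slope_comparisons,
        bundle=bundle,
        provenance=provenance,
    )
    result.report_text = _render_report(result, table)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        behavioral.to_csv(out / "behavioral_summary.tsv", sep="\t", index=False)
        contrasts.to_csv(out / "first_level_contrasts.tsv", sep="\t", index=False)
        slope_comparisons.to_csv(out / "slope_comparisons.tsv", sep="\t", index=False)
        for roi, rep in second_level.items():
            rep.as_frame().to_csv(out / f"second_level_{roi}.tsv", sep="\t", index=False)
        (out / "report.txt").write_text(result.report_text)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
        if config.write_bundle_files:
            write_bundle(bundle, out / "cohort_bundle")
    return result


def _render_report(result: RunResult, table: pd.DataFrame) -> str:
    """Plain-text summary mirroring the study's results tables."""
    b = result.behavioral
    cohort = result.bundle.cohort
    men = cohort[cohort["gender"] == "M"]
    women = cohort[cohort["gender"] == "F"]
    t, dof, p, d = two_sample_t(women["ha"], men["ha"])
    n_sig = int((b["seq_effect_p"] < 0.05).sum())

    lines = [
        "Synthetic stop-signal study report",
        "==================================",
        f"n = {len(cohort)} subjects ({(cohort['gender'] == 'F').sum()} women)",
        "",
        "Trait scores (mean +- SD):",
        f"  NS {cohort['ns'].mean():.1f} +- {cohort['ns'].std(ddof=1):.1f}"
        f" | HA {cohort['ha'].mean():.1f} +- {cohort['ha'].std(ddof=1):.1f}"
        f" | RD {cohort['rd'].mean():.1f} +- {cohort['rd'].std(ddof=1):.1f}",
        f"  HA gender difference (women - men): t({dof}) = {t:.3f}, p = {p:.3f}, d = {d:.3f}",
        "",
        "Task performance:",
        f"  go response rate {100 * b['go_response_rate'].mean():.1f}"
        f" +- {100 * b['go_response_rate'].std(ddof=1):.1f} %",
        f"  stop success rate {100 * b['ss_rate'].mean():.1f}"
        f" +- {100 * b['ss_rate'].std(ddof=1):.1f} %",
        f"  median GoRT {b['median_gort_ms'].mean():.0f} +- {b['median_gort_ms'].std(ddof=1):.0f} ms",
        f"  SSRT {b['ssrt_ms'].mean():.0f} +- {b['ssrt_ms'].std(ddof=1):.0f} ms",
        f"  sequential effect r {b['seq_effect_r'].mean():.2f}"
        f" +- {b['seq_effect_r'].std(ddof=1):.2f}; significant in {n_sig}/{len(b)} subjects",
        "",
        "Second-level trait regressions (GS_pstop>0 contrast):",
    ]
    for roi, rep in result.second_level.items():
        frame = rep.as_frame().set_index("predictor")
        trait = result.bundle.config.rois[roi].trait
        row = frame.loc[trait]
        r_simple, p_simple = correlate(table[trait], table[roi])
        lines.append(
            f"  {roi}: {trait.upper()} coef {row['coef']:+.4f} (t = {row['t']:.2f},"
            f" p = {row['p']:.4f}); simple r = {r_simple:.3f} (p = {p_simple:.4f},"
            f" R^2 = {100 * r_simple**2:.1f} %)"
        )
    lines.append("")
    lines.append("Gender slope comparisons (trait vs contrast):")
    for _, row in result.slope_comparisons.iterrows():
        lines.append(
            f"  {row['roi']}: t({int(row['dof'])}) = {row['t']:.3f}, p = {row['p']:.3f}"
        )
    return "\n".join(lines) + "\n"
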