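"""Orchestration: image pipeline (register → fit → VOI metrics) and the
cohort-level statistical analysis.

``run_image_pipeline`` turns per-animal baseline/follow-up DWI sessions
(files or phantom specifications) into a cohort table; ``run_cohort_analysis``
turns a cohort table into the full study report: per-group median ± SD
summaries, paired and unpaired rank tests, ROC curves with Youden-optimal
thresholds for ΔADC / ΔVOL / FLDA, DeLong AUC comparisons and per-group
Pearson correlations.  The report is a pure function of the cohort table:
every number in it is recomputable from the saved CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adc import compute_adc_map
from .errors import DegenerateInputError, DWIResponseError, ValidationError
from .io_model import CohortTable, read_dwi_study, read_voi_mask
from .registration import register_series
from .rocflda import (
    GREATER,
    LESS,
    delong_test,
    fit_flda,
    optimal_threshold,
    project_flda,
    roc_curve,
)
from .stats import mann_whitney_u, pearson_correlation, wilcoxon_signed_rank
from .synthetic import PhantomConfig, generate_phantom
from .voi import build_records, mask_volume, median_adc

_SUMMARY_FIELDS = ("adc_b", "adc_f", "d_adc", "vol_b", "vol_f", "d_vol_pct")


@dataclass
class StudyReport:
    """All cohort-level results, with full numeric precision.

    ``group_summaries``: per group and per field, {"median", "sd", "n"}.
    ``intragroup``/``intergroup``: test results as {"statistic", "p_value",
    "method", "exact"} dicts; degenerate statistics are reported as
    {"error": ...} fields rather than silently omitted.
    ``roc``: per classifier {"auc", "threshold", "sens", "spec", "accuracy",
    "youden_j", "direction"}.  ``flda``: fitted weights and scaling.
    ``delong``: pairwise AUC comparisons.  ``pearson``: per-group ΔADC-ΔVOL
    correlation.
    """

    group_summaries: dict = field(default_factory=dict)
    intragroup: dict = field(default_factory=dict)
    intergroup: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)
    flda: dict = field(default_factory=dict)
    delong: dict = field(default_factory=dict)
    pearson: dict = field(default_factory=dict)
    n_therapy: int = 0
    n_control: int = 0

    def to_dict(self) -> dict:
        return {
            "n_therapy": self.n_therapy,
            "n_control": self.n_control,
            "group_summaries": self.group_summaries,
            "intragroup": self.intragroup,
            "intergroup": self.intergroup,
            "roc": self.roc,
            "flda": self.flda,
            "delong": self.delong,
            "pearson": self.pearson,
        }

    def to_markdown(self) -> str:
        """Human-readable report with the study's table layout (display
        rounding only; the dict/JSON form keeps full precision)."""
        lines = [
            "# Study report",
            "",
            f"Animals: therapy n = {self.n_therapy}, control n = {self.n_control}",
            "",
            "## Group summaries (median ± SD)",
            "",
            "| Group | " + " | ".join(_SUMMARY_FIELDS) + " |",
            "|" + "---|" * (len(_SUMMARY_FIELDS) + 1),
        ]
        for grp in ("therapy", "control"):
            cells = []
            for f_ in _SUMMARY_FIELDS:
                s = self.group_summaries[grp][f_]
                cells.append(f"{s['median']:.3g}±{s['sd']:.3g}")
            lines.append(f"| {grp} | " + " | ".join(cells) + " |")
        lines += ["", "## ROC analysis", "",
                  "| Classifier | AUC | Threshold | Sens | Spec | Accuracy |",
                  "|---|---|---|---|---|---|"]
        for name, r in self.roc.items():
            lines.append(
                f"| {name} | {r['auc']:.3f} | {r['threshold']:.4g} | "
                f"{100 * r['sens']:.1f}% | {100 * r['spec']:.1f}% | "
                f"{100 * r['accuracy']:.1f}% |"
            )
        lines += ["", "## Tests", ""]
        for section, entries in (("intragroup", self.intragroup),
                                 ("intergroup", self.intergroup),
                                 ("delong", self.delong),
                                 ("pearson", self.pearson)):
            for key, res in entries.items():
                if "error" in res:
                    lines.append(f"- {section}.{key}: degenerate ({res['error']})")
                else:
                    lines.append(
                        f"- {section}.{key}: statistic = {res['statistic']:.4g}, "
                        f"p = {res['p_value']:.4g}"
                    )
        if self.flda:
            lines += ["", "## FLDA", "",
                      f"score = {self.flda['w_dvol']:.4g}·ΔVOL[%] + "
                      f"{self.flda['w_dadc']:.4g}·ΔADC[1e-3 mm²/s] "
                      f"({self.flda['scaling']}; threshold {self.flda['threshold']:.4g}, "
                      "below = therapy)"]
        return "\n".join(lines) + "\n"


def _result_dict(fn, *args, **kwargs) -> dict:
    """Run a statistic, mapping degenerate inputs to a flagged field."""
    try:
        res = fn(*args, **kwargs)
    except (DegenerateInputError, ValidationError) as exc:
        return {"error": str(exc)}
    return {"statistic": res.statistic, "p_value": res.p_value,
            "method": res.method, "exact": res.exact}


def run_cohort_analysis(cohort: CohortTable) -> StudyReport:
    """Compute the full statistical report of a two-group cohort.

    Within each group: paired Wilcoxon of baseline vs. follow-up (ADC and
    volume).  Between groups: Mann-Whitney U on ΔADC, ΔVOL and the raw
    follow-up values.  ROC curves with Youden-optimal thresholds for ΔADC
    (greater = therapy), ΔVOL (lower = therapy) and the FLDA score (lower =
    therapy); DeLong comparisons between all three; per-group Pearson
    correlation between ΔADC and ΔVOL.
    """
    n_t, n_c = cohort.group_counts
    if n_t < 2 or n_c < 2:
        raise ValidationError("each group must contain at least 2 animals")
    report = StudyReport(n_therapy=n_t, n_control=n_c)

    for grp in ("therapy", "control"):
        report.group_summaries[grp] = {}
        for f_ in _SUMMARY_FIELDS:
            vals = cohort.column(f_, grp)
            report.group_summaries[grp][f_] = {
                "median": float(np.median(vals)),
                "sd": float(np.std(vals, ddof=1)),
                "n": int(vals.size),
            }
        report.intragroup[f"{grp}_adc"] = _result_dict(
            wilcoxon_signed_rank, cohort.column("adc_f", grp), cohort.column("adc_b", grp)
        )
        report.intragroup[f"{grp}_vol"] = _result_dict(
            wilcoxon_signed_rank, cohort.column("vol_f", grp), cohort.column("vol_b", grp)
        )
        try:
            res = pearson_correlation(
                cohort.column("d_adc", grp), cohort.column("d_vol_pct", grp)
            )
            report.pearson[grp] = {"r": res.statistic, "statistic": res.statistic,
                                   "p_value": res.p_value}
        except (DegenerateInputError, ValidationError) as exc:
            report.pearson[grp] = {"error": str(exc)}

    for f_ in ("d_adc", "d_vol_pct", "adc_f", "vol_f"):
        report.intergroup[f_] = _result_dict(
            mann_whitney_u, cohort.column(f_, "therapy"), cohort.column(f_, "control")
        )

    labels = np.asarray([r.group for r in cohort.records])
    d_adc = cohort.column("d_adc")
    d_vol = cohort.column("d_vol_pct")
    features = np.column_stack([d_vol, d_adc])

    classifiers = {"d_adc": (d_adc, GREATER), "d_vol_pct": (d_vol, LESS)}
    try:
        model = fit_flda(features, labels)
        report.flda = {"w_dvol": model.w_dvol, "w_dadc": model.w_dadc,
                       "scaling": model.scaling, "threshold": model.threshold,
                       "orientation": model.orientation}
        classifiers["flda"] = (project_flda(model, features), LESS)
    except (DegenerateInputError, ValidationError) as exc:
        report.flda = {"error": str(exc)}

    for name, (scores, direction) in classifiers.items():
        roc = roc_curve(scores, labels, direction=direction)
        best = optimal_threshold(roc)
        report.roc[name] = {
            "auc": roc.auc, "threshold": best.threshold, "sens": best.sens,
            "spec": best.spec, "accuracy": best.accuracy,
            "youden_j": best.youden_j, "direction": direction,
        }

    pairs = [("flda", "d_adc"), ("flda", "d_vol_pct"), ("d_adc", "d_vol_pct")]
    for a, b in pairs:
        if a not in classifiers or b not in classifiers:
            continue
        sa, da = classifiers[a]
        sb, db = classifiers[b]
        report.delong[f"{a}_vs_{b}"] = _result_dict(
            delong_test, sa, sb, labels, directions=(da, db)
        )
    return report


# ---------------------------------------------------------------------------
# image pipeline
# ---------------------------------------------------------------------------

def _load_session(session: dict):
    """One imaging session from a config entry: either file paths
    ({"image", "bvals", "mask"}) or a phantom spec ({"phantom": {...}}).
    Returns (study, voi_mask)."""
    if "phantom" in session:
        config = PhantomConfig(**session["phantom"])
        study, voi, _ = generate_phantom(config)
        return study, voi
    study = read_dwi_study(session["image"], session["bvals"])
    voi = read_voi_mask(session["mask"], slice_thickness=study.slice_thickness,
                        slice_gap=study.slice_gap)
    return study, voi


def _session_metrics(session: dict, register: bool) -> tuple[float, float]:
    """(median tumor ADC, tumor volume) of one session.

    The volume comes from the session's T2-geometry mask when configured
    ("t2_mask" path); otherwise from the DWI VOI mask.
    """
    study, voi = _load_session(session)
    if register and study.n_bvalues > 1:
        study, _ = register_series(study, reference_index=0)
    adc_map = compute_adc_map(study, mask=voi)
    adc = median_adc(adc_map, voi)
    if "t2_mask" in session:
        vol_mask = read_voi_mask(session["t2_mask"])
        volume = mask_volume(vol_mask)
    else:
        volume = mask_volume(voi)
    return adc, volume


def run_image_pipeline(config: dict) -> tuple[CohortTable, list[dict]]:
    """Process every animal of an image-pipeline config into a cohort table.

    ``config["animals"]`` lists entries with keys ``id``, ``group``,
    ``baseline`` and ``followup`` (each a session as in :func:`_load_session`).
    ``config["register"]`` (default True) toggles b-value registration.
    A failing animal is recorded in the returned failure manifest with its
    stage and error; the remaining animals are still processed.
    """
    if "animals" not in config or not config["animals"]:
        raise ValidationError("config must list at least one animal")
    register = bool(config.get("register", True))
    measurements = []
    failures: list[dict] = []
    for entry in config["animals"]:
        animal_id = str(entry.get("id", f"animal{len(measurements)}"))
        try:
            adc_b, vol_b = _session_metrics(entry["baseline"], register)
            adc_f, vol_f = _session_metrics(entry["followup"], register)
        except (DWIResponseError, OSError, KeyError, TypeError) as exc:
            failures.append({"animal_id": animal_id,
                             "error": f"{type(exc).__name__}: {exc}"})
            continue
        measurements.append(
            {"animal_id": animal_id, "group": entry["group"],
             "adc_b": adc_b, "adc_f": adc_f, "vol_b": vol_b, "vol_f": vol_f}
        )
    table = build_records(measurements, provenance=str(config.get("name", "image-pipeline")))
    return table, failures
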