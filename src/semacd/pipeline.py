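"""End-to-end study pipeline: generate -> score -> resolve -> report.

The report mirrors the Results layout of a central-reading validation study:

* **validity** — Spearman correlation of the per-video final (median) SEMA-CD
  against the comparator SES-CD: overall, per cohort, per baseline severity
  stratum (strata defined by the SES-CD band of the pre-treatment video, so
  stratum sizes sum to the baseline-video count), and on per-patient change
  scores.
* **reliability** — inter-rater one-way ICC over the primary (and
  adjudication) reads, pooled reader-pair mean differences, pairwise and
  pooled weighted kappas on the severity-band scale, and intra-rater ICC and
  mean difference over the (initial read, re-read) pairs.
* **feasibility** — correlations by video-quality category, the count of
  non-scorable videos, and the count of partial (ileum-not-assessed) videos.
* **usability** — a descriptive tally of the simulated 7-point
  ease-of-scoring ratings (one per video reading); no inference.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as scio
from .reliability import (
    POOLED,
    ReliabilityError,
    change_score_correlation,
    icc_oneway,
    pool_kappas,
    pooled_mean_difference,
    spearman_ci,
    weighted_kappa,
)
from .scoring import SEMA_BANDS, ScoringError, classify_sema, classify_ses
from .synthetic_data import USABILITY_SCALE, GeneratorConfig, StudyData, generate_study

logger = logging.getLogger(__name__)

SEMA_BAND_LABELS = [b[0] for b in SEMA_BANDS]


def _corr_entry(result) -> dict:
    return {
        "rho": result.rho,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "n": result.n,
        "stratum": result.stratum_label,
        "meets_threshold": result.meets_threshold,
    }


def _corr_or_none(x, y, label) -> dict:
    try:
        return _corr_entry(spearman_ci(x, y, stratum_label=label))
    except ReliabilityError as exc:
        return {"rho": None, "ci_low": None, "ci_high": None, "n": int(len(x)),
                "stratum": label, "meets_threshold": False, "note": str(exc)}


def _icc_entry(result) -> dict:
    return {
        "icc": result.icc,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "variance_between": result.variance_between,
        "variance_within": result.variance_within,
        "n_groups": result.n_groups,
        "n_obs": result.n_obs,
        "method": result.method,
        "band": result.band,
    }


def _kappa_entry(result) -> dict:
    return {
        "reader_pair": list(result.reader_pair),
        "kappa": result.kappa,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "n": result.n,
        "weight_scheme": result.weight_scheme,
        "band": result.band,
    }


def build_report(study: StudyData, kappa_scheme: str = "linear") -> dict:
    """Compute the full validation report from one study's tables."""
    cfg = study.config
    scored = scio.score_ratings_frame(study.ratings)
    ses = scio.ses_totals_from_frame(study.ses)
    resolved = study.resolved
    truth = study.truth

    # Per-video analysis table: final median SEMA-CD + comparator SES-CD.
    videos = (
        resolved[["video_id", "final_score", "adjudicated"]]
        .merge(ses, on="video_id")
        .merge(
            truth[["video_id", "patient_id", "timepoint", "cohort", "video_quality"]],
            on="video_id",
        )
    )
    videos = videos.sort_values("video_id").reset_index(drop=True)

    # --- validity -----------------------------------------------------------
    validity = {
        "overall": _corr_or_none(videos["final_score"], videos["ses_total"], "overall")
    }
    for cohort, grp in videos.groupby("cohort"):
        validity[cohort] = _corr_or_none(grp["final_score"], grp["ses_total"], cohort)

    pre = videos[videos["timepoint"] == "pre"].copy()
    pre["severity_stratum"] = pre["ses_total"].map(classify_ses)
    strata = []
    for label in ("inactive", "mild", "moderate", "severe"):
        grp = pre[pre["severity_stratum"] == label]
        if len(grp) == 0:
            strata.append({"rho": None, "ci_low": None, "ci_high": None, "n": 0,
                           "stratum": label, "meets_threshold": False, "note": "empty stratum"})
        else:
            strata.append(_corr_or_none(grp["final_score"], grp["ses_total"], label))
    validity["by_baseline_severity"] = strata
    validity["baseline_videos"] = int(len(pre))

    wide = videos.pivot_table(index="patient_id", columns="timepoint",
                              values=["final_score", "ses_total"], aggfunc="first")
    pre_post = pd.DataFrame(
        {
            "sema_pre": wide[("final_score", "pre")],
            "sema_post": wide[("final_score", "post")],
            "ses_pre": wide[("ses_total", "pre")],
            "ses_post": wide[("ses_total", "post")],
        }
    )
    try:
        validity["change_score"] = _corr_entry(change_score_correlation(pre_post))
    except ReliabilityError as exc:
        validity["change_score"] = {"rho": None, "n": int(len(pre_post)), "note": str(exc)}

    # --- reliability --------------------------------------------------------
    primaries = scored[scored["occasion"].isin(["primary_1", "primary_2", "adjudication"])]
    inter_icc = icc_oneway(
        primaries.rename(columns={"sema_total": "score"}), "video_id", "score"
    )

    # Reader-pair mean differences, fixed order: lower reader id minus higher.
    pair_strata, pair_bands = [], []
    prim = scored[scored["occasion"].isin(["primary_1", "primary_2"])]
    pivot = prim.pivot(index="video_id", columns="occasion",
                       values=["reader_id", "sema_total", "severity_band"])
    pivot = pivot.dropna(subset=[("sema_total", "primary_1"), ("sema_total", "primary_2")])
    r1 = pivot[("reader_id", "primary_1")]
    r2 = pivot[("reader_id", "primary_2")]
    pair_label = r1.combine(r2, lambda a, b: "-".join(sorted([str(a), str(b)])))
    diffs = pivot[("sema_total", "primary_1")] - pivot[("sema_total", "primary_2")]
    # sign convention: id-sorted first reader minus second
    sign = np.where(r1 <= r2, 1.0, -1.0)
    kappas = []
    for label in sorted(pair_label.unique()):
        mask = (pair_label == label).to_numpy()
        pair_strata.append((label, (diffs.to_numpy(float) * sign)[mask]))
        a = np.where(sign[mask] > 0,
                     pivot[("severity_band", "primary_1")].to_numpy()[mask],
                     pivot[("severity_band", "primary_2")].to_numpy()[mask])
        b = np.where(sign[mask] > 0,
                     pivot[("severity_band", "primary_2")].to_numpy()[mask],
                     pivot[("severity_band", "primary_1")].to_numpy()[mask])
        try:
            kappas.append(
                weighted_kappa(a, b, SEMA_BAND_LABELS, scheme=kappa_scheme,
                               reader_pair=tuple(label.split("-")))
            )
        except ReliabilityError as exc:
            logger.warning("kappa undefined for pair %s: %s", label, exc)
        pair_bands.append(label)

    inter_diff = pooled_mean_difference(pair_strata)
    pooled_kappa = pool_kappas(kappas) if kappas else None

    # Intra-rater: (initial read, reread) pairs of the same reader.
    rereads = scored[scored["occasion"] == "reread"][["video_id", "reader_id", "sema_total"]]
    initial = prim[["video_id", "reader_id", "sema_total"]].rename(
        columns={"sema_total": "initial_total"}
    )
    intra = rereads.merge(initial, on=["video_id", "reader_id"], how="inner")
    intra_long = pd.concat(
        [
            intra[["video_id", "initial_total"]].rename(columns={"initial_total": "score"}),
            intra[["video_id", "sema_total"]].rename(columns={"sema_total": "score"}),
        ]
    )
    reliability = {
        "inter_rater_icc": _icc_entry(inter_icc),
        "inter_rater_mean_difference": {
            "mean_diff": inter_diff.mean_diff,
            "ci_low": inter_diff.ci_low,
            "ci_high": inter_diff.ci_high,
            "strata": [
                {"pair": s[0], "mean": s[1], "variance_of_mean": s[2], "n": s[3]}
                for s in inter_diff.strata
            ],
        },
        "pairwise_kappas": [_kappa_entry(k) for k in kappas],
        "pooled_kappa": _kappa_entry(pooled_kappa) if pooled_kappa else None,
        "adjudication_rate": float(resolved["adjudicated"].mean()),
        "n_adjudicated": int(resolved["adjudicated"].sum()),
    }
    if len(intra) >= 2:
        reliability["intra_rater_icc"] = _icc_entry(
            icc_oneway(intra_long, "video_id", "score")
        )
        intra_strata = [
            (rid, (grp["initial_total"] - grp["sema_total"]).to_numpy(float))
            for rid, grp in intra.groupby("reader_id")
        ]
        try:
            intra_diff = pooled_mean_difference(intra_strata)
            reliability["intra_rater_mean_difference"] = {
                "mean_diff": intra_diff.mean_diff,
                "ci_low": intra_diff.ci_low,
                "ci_high": intra_diff.ci_high,
                "n_rereads": int(len(intra)),
            }
        except ReliabilityError as exc:
            reliability["intra_rater_mean_difference"] = {"note": str(exc)}
    else:
        reliability["intra_rater_icc"] = None
        reliability["intra_rater_mean_difference"] = None

    # --- feasibility --------------------------------------------------------
    feasibility = {"by_quality": []}
    for quality, grp in videos.groupby("video_quality"):
        feasibility["by_quality"].append(
            _corr_or_none(grp["final_score"], grp["ses_total"], quality)
        )
        feasibility[f"prop_{quality}"] = float(len(grp) / len(videos))
    feasibility["n_nonscorable"] = int(resolved["final_score"].isna().sum())
    feasibility["n_partial_ileum_not_assessed"] = int(
        (~study.truth["ileum_assessed"].astype(bool)).sum()
    )

    # --- usability (descriptive tally of simulated 7-point ratings) ---------
    usa_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    probs = np.array([cfg.usability_mix[c] for c in USABILITY_SCALE])
    n_readings = len(scored)
    draws = usa_rng.choice(len(USABILITY_SCALE), size=n_readings, p=probs)
    counts = np.bincount(draws, minlength=len(USABILITY_SCALE))
    usability = {
        "n_readings": int(n_readings),
        "tally": {c: int(k) for c, k in zip(USABILITY_SCALE, counts)},
        "percent": {c: float(100.0 * k / n_readings) for c, k in zip(USABILITY_SCALE, counts)},
    }
    usability["percent_easier"] = float(
        sum(usability["percent"][c] for c in USABILITY_SCALE[:3])
    )

    return {
        "validity": validity,
        "reliability": reliability,
        "feasibility": feasibility,
        "usability": usability,
        "counts": {
            "n_patients": int(study.patients.shape[0]),
            "n_videos": int(len(videos)),
            "n_readings": int(len(scored)),
            "n_rereads": int(len(rereads)),
        },
        "provenance": {"config_hash": cfg.config_hash(), "seed": int(cfg.seed)},
    }


def report_table(report: dict) -> pd.DataFrame:
    """Flatten the report into one row per statistic (2-dp display rounding)."""
    rows = []

    def add(section, name, est, lo, hi, n, flag):
        rows.append(
            {
                "section": section,
                "statistic": name,
                "estimate": None if est is None else round(float(est), 2),
                "ci_low": None if lo is None else round(float(lo), 2),
                "ci_high": None if hi is None else round(float(hi), 2),
                "n": n,
                "band_or_flag": flag,
            }
        )

    v = report["validity"]
    for key in ("overall", "pediatric", "adult"):
        if key in v:
            c = v[key]
            add("validity", f"spearman_{key}", c["rho"], c["ci_low"], c["ci_high"],
                c["n"], "meets_0.6" if c["meets_threshold"] else "below_0.6")
    for c in v["by_baseline_severity"]:
        add("validity", f"spearman_{c['stratum']}", c["rho"], c.get("ci_low"),
            c.get("ci_high"), c["n"], "meets_0.6" if c.get("meets_threshold") else "below_0.6")
    c = v["change_score"]
    add("validity", "spearman_change", c.get("rho"), c.get("ci_low"), c.get("ci_high"),
        c.get("n"), "meets_0.6" if c.get("meets_threshold") else "below_0.6")

    r = report["reliability"]
    i = r["inter_rater_icc"]
    add("reliability", "inter_rater_icc", i["icc"], i["ci_low"], i["ci_high"],
        i["n_groups"], i["band"])
    d = r["inter_rater_mean_difference"]
    add("reliability", "inter_rater_mean_difference", d["mean_diff"], d["ci_low"],
        d["ci_high"], sum(s["n"] for s in d["strata"]), "")
    for k in r["pairwise_kappas"]:
        add("reliability", f"kappa_{'-'.join(k['reader_pair'])}", k["kappa"],
            k["ci_low"], k["ci_high"], k["n"], k["band"])
    if r["pooled_kappa"]:
        k = r["pooled_kappa"]
        add("reliability", "pooled_kappa", k["kappa"], k["ci_low"], k["ci_high"],
            k["n"], k["band"])
    if r["intra_rater_icc"]:
        i = r["intra_rater_icc"]
        add("reliability", "intra_rater_icc", i["icc"], i["ci_low"], i["ci_high"],
            i["n_groups"], i["band"])
    if r["intra_rater_mean_difference"] and "mean_diff" in r["intra_rater_mean_difference"]:
        d = r["intra_rater_mean_difference"]
        add("reliability", "intra_rater_mean_difference", d["mean_diff"], d["ci_low"],
            d["ci_high"], d.get("n_rereads"), "")
    add("reliability", "adjudication_rate", r["adjudication_rate"], None, None,
        r["n_adjudicated"], "")

    f = report["feasibility"]
    for c in f["by_quality"]:
        add("feasibility", f"spearman_quality_{c['stratum']}", c["rho"], c.get("ci_low"),
            c.get("ci_high"), c["n"], "meets_0.6" if c.get("meets_threshold") else "below_0.6")
    add("feasibility", "n_nonscorable", f["n_nonscorable"], None, None, None, "")

    u = report["usability"]
    add("usability", "percent_easier", u["percent_easier"], None, None, u["n_readings"], "")
    return pd.DataFrame(rows)


def write_report(report: dict, study: StudyData, outdir) -> None:
    """Write report JSON, the flat table, and the two scatter-plot data files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report_table(report).to_csv(out / "report_table.csv", index=False)

    ses = scio.ses_totals_from_frame(study.ses)
    videos = study.resolved[["video_id", "final_score"]].merge(ses, on="video_id")
    videos = videos.sort_values("video_id")
    videos.rename(columns={"final_score": "sema_final"}).to_csv(
        out / "scatter_sema_vs_ses.csv", index=False
    )
    merged = videos.merge(
        study.truth[["video_id", "patient_id", "timepoint"]], on="video_id"
    )
    wide = merged.pivot_table(index="patient_id", columns="timepoint",
                              values=["final_score", "ses_total"], aggfunc="first")
    pd.DataFrame(
        {
            "patient_id": wide.index,
            "delta_sema": (wide[("final_score", "post")] - wide[("final_score", "pre")]).values,
            "delta_ses": (wide[("ses_total", "post")] - wide[("ses_total", "pre")]).values,
        }
    ).to_csv(out / "scatter_change.csv", index=False)


def run_study(config: GeneratorConfig, outdir: Optional[str] = None) -> dict:
    """Generate a study, build the report, and optionally write all outputs."""
    t0 = time.perf_counter()
    study = generate_study(config)
    logger.info("generate: %.2fs", time.perf_counter() - t0)
    t0 = time.perf_counter()
    report = build_report(study)
    logger.info("report: %.2fs", time.perf_counter() - t0)
    if outdir is not None:
        study.write(outdir)
        write_report(report, study, outdir)
    return report


def resolve_frame(scored: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Recompute the resolved per-video table from a scored ratings CSV.

    File-based counterpart of the in-memory resolution path: uses the
    adjudication rows already present in the CSV, and errors if the >threshold
    rule demands an adjudication that the file does not contain.
    """
    rows = []
    for video_id, grp in scored.groupby("video_id", sort=True):
        by_occ = {occ: g for occ, g in grp.groupby("occasion")}
        try:
            t1 = float(by_occ["primary_1"]["sema_total"].iloc[0])
            t2 = float(by_occ["primary_2"]["sema_total"].iloc[0])
        except KeyError as exc:
            raise ScoringError(f"video {video_id!r}: missing {exc} read") from exc
        adjudicated = abs(t1 - t2) > threshold
        t3 = None
        if adjudicated:
            if "adjudication" not in by_occ:
                raise ScoringError(
                    f"video {video_id!r}: adjudication required (|{t1}-{t2}| > {threshold}) "
                    "but no adjudication read present"
                )
            t3 = float(by_occ["adjudication"]["sema_total"].iloc[0])
            final = float(np.median([t1, t2, t3]))
        else:
            final = (t1 + t2) / 2.0
        reread_total = (
            float(by_occ["reread"]["sema_total"].iloc[0]) if "reread" in by_occ else None
        )
        rows.append(
            {
                "video_id": video_id,
                "total_read1": t1,
                "total_read2": t2,
                "total_adjud": t3,
                "adjudicated": adjudicated,
                "final_score": final,
                "reread_total": reread_total,
            }
        )
    return pd.DataFrame(rows)
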