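"""Batch orchestration: manifest-driven feature extraction and cohort statistics.

The extraction entry point turns a manifest of labeled recordings
(subject, task, repetition, path) into one row of the 29 acoustic features
per subject, averaging the two protocol repetitions per feature; the
statistics entry point runs the full cohort analysis (group comparison,
sex-stratified z-scores, the six-feature Gaussian Naive Bayes classifier,
stage comparisons and covariate-adjusted correlations) on a feature table
joined with clinical metadata.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import articulation, cohort, ddk, phonation, prosody
from .audio_core import AudioRecording, lpc_formants, read_wav, track_f0, trim_silence, voicing_segments
from .errors import PdspeechError
from .phonation import vowel_space_area
from .synth import SELECTED_FEATURES

MANIFEST_COLUMNS = ("subject_id", "task", "repetition", "path")

_VOWEL_TASKS = {"vowel_a": "a", "vowel_i": "i", "vowel_u": "u"}


def _vowel_f1f2(rec: AudioRecording) -> tuple[float, float]:
    """Median F1/F2 over voiced frames of a sustained vowel."""
    f0 = track_f0(rec)
    segments = voicing_segments(f0)
    if not segments:
        return float("nan"), float("nan")
    f1_track, f2_track = lpc_formants(rec, n_formants=3)[:2]
    f1 = phonation._median_in_segments(f1_track, segments)
    f2 = phonation._median_in_segments(f2_track, segments)
    return f1, f2


def analyze_recording(rec: AudioRecording, n_syllables: int = 105) -> dict:
    """Feature dict for one recording, keyed by canonical feature names.

    Sustained /i/ and /u/ contribute only their formants (keys ``F1_i`` ...),
    which feed the per-subject vowel space area.
    """
    trimmed, _ = trim_silence(rec)
    if rec.task == "vowel_a":
        feats = phonation.phonation_features(trimmed)
        out = {
            k: getattr(feats, k)
            for k in ("F0", "F0std", "vF0", "Ampstd", "vAmp", "MPT", "HNR")
        }
        out["F1_a"], out["F2_a"] = feats.F1, feats.F2
        return out
    if rec.task in ("vowel_i", "vowel_u"):
        suffix = _VOWEL_TASKS[rec.task]
        f1, f2 = _vowel_f1f2(trimmed)
        return {f"F1_{suffix}": f1, f"F2_{suffix}": f2}
    if rec.task == "ddk_pa":
        feats, _ = ddk.analyze_ddk(trimmed)
        out = {k: getattr(feats, k) for k in
               ("DDKavr", "DDKavp", "DDKsdp", "DDKcvp", "DDKjit", "DDKsdi", "DDKcvi")}
        out["VOT"] = feats.VOT if feats.VOT is not None else float("nan")
        return out
    if rec.task == "iu_alternation":
        feats, _ = articulation.analyze_iu(trimmed)
        return {k: getattr(feats, k) for k in
                ("F2magn", "F2rate", "F2reg", "F2aver", "F2min", "F2max")}
    if rec.task == "passage":
        feats, _ = prosody.analyze_passage(rec, n_syllables=n_syllables)
        return {k: getattr(feats, k) for k in
                ("TotalDur", "NSR", "DPI", "rF0", "rSTD", "rvF0", "rvAm")}
    raise PdspeechError(f"no analysis defined for task {rec.task!r}")


def subject_features(recordings: list[AudioRecording], n_syllables: int = 105) -> dict:
    """Combine one subject's recordings into their feature row.

    Repetitions of the same task are analyzed independently and averaged per
    feature; the vowel space area is computed once from the repetition-mean
    formants of /a/, /i/ and /u/.
    """
    collected: dict[str, list[float]] = {}
    errors: list[str] = []
    for rec in recordings:
        try:
            for key, val in analyze_recording(rec, n_syllables=n_syllables).items():
                collected.setdefault(key, []).append(val)
        except PdspeechError as exc:
            errors.append(f"{rec.task} rep {rec.repetition}: {exc}")
    row = {k: float(np.nanmean(v)) if np.any(np.isfinite(v)) else float("nan")
           for k, v in collected.items()}
    formant_keys = ["F1_a", "F2_a", "F1_i", "F2_i", "F1_u", "F2_u"]
    formants = [row.pop(k, float("nan")) for k in formant_keys]
    try:
        row["VowelArea"] = vowel_space_area(*formants)
    except PdspeechError:
        row["VowelArea"] = float("nan")
    if errors:
        row["_errors"] = "; ".join(errors)
    return row


def extract_features(
    manifest: pd.DataFrame, n_syllables: int = 105
) -> pd.DataFrame:
    """Extract the full feature table from a manifest of recordings.

    The manifest needs columns (subject_id, task, repetition, path).  Every
    subject yields one row with the 29 feature columns; missing tasks leave
    NaN cells and unreadable files are recorded in an ``_errors`` column while
    the run continues.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise PdspeechError(f"manifest lacks columns {missing}")
    rows = {}
    for subject_id, group in manifest.groupby("subject_id", sort=True):
        recs = []
        errors = []
        for _, entry in group.iterrows():
            try:
                rec = read_wav(entry["path"])
            except PdspeechError as exc:
                errors.append(f"{entry['path']}: {exc}")
                continue
            recs.append(
                AudioRecording(
                    rec.samples,
                    rec.sample_rate,
                    task=entry["task"],
                    subject_id=str(subject_id),
                    repetition=int(entry["repetition"]),
                )
            )
        tasks = {r.task for r in recs}
        reps = {r.task: len([x for x in recs if x.task == r.task]) for r in recs}
        if any(v == 1 for v in reps.values()):
            warnings.warn(f"{subject_id}: single repetition for {sorted(k for k, v in reps.items() if v == 1)}")
        row = subject_features(recs, n_syllables=n_syllables)
        if errors:
            row["_errors"] = "; ".join([row.get("_errors", "")] + errors).strip("; ")
        rows[subject_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    ordered = [c for c in cohort.FEATURE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    return table[ordered + extra]


def run_stats(cohort_table: pd.DataFrame, seed: int = 0, k_folds: int = 5) -> dict:
    """Full cohort analysis on a merged feature + metadata table.

    Returns the group comparison (with FDR-adjusted p-values), the
    z-normalized table, the feature ranking, the six-feature classifier
    report, stage comparisons for the selected features, and partial
    correlations of the selected features with UPDRS-III adjusted for age,
    sex, MoCA, height and weight.
    """
    comparison = cohort.compare_groups(cohort_table)
    comparison["p_fdr"] = cohort.fdr_adjust(comparison["p_value"].to_numpy())
    znormed = cohort.znormalize(cohort_table, features=list(comparison.index))
    ranking = cohort.rank_features(comparison, cohort_table[list(comparison.index)])

    clf_feats = [f for f in SELECTED_FEATURES if f in cohort_table.columns]
    clf_data = znormed.dropna(subset=clf_feats)
    X = clf_data[clf_feats].to_numpy(dtype=float)
    y = (clf_data["group"] == "PD").astype(int).to_numpy()
    report = cohort.nb_classify_cv(X, y, k=k_folds, seed=seed)

    stages = {}
    for f in clf_feats:
        try:
            stages[f] = cohort.stage_comparison(cohort_table, f)
        except PdspeechError:
            continue

    correlations = []
    pd_rows = cohort_table[cohort_table["group"] == "PD"]
    cov_cols = ["age", "MoCA", "height", "weight"]
    if all(c in pd_rows.columns for c in cov_cols + ["sex", "UPDRS_III"]):
        cov = np.column_stack(
            [pd_rows[c].to_numpy(dtype=float) for c in cov_cols]
            + [(pd_rows["sex"] == "M").astype(float).to_numpy()]
        )
        for f in clf_feats:
            try:
                r, p = cohort.partial_correlation(
                    pd_rows[f].to_numpy(dtype=float),
                    pd_rows["UPDRS_III"].to_numpy(dtype=float),
                    cov,
                )
            except PdspeechError:
                continue
            correlations.append({"feature": f, "r": r, "p_value": p})
    corr_df = pd.DataFrame(correlations)
    if len(corr_df):
        corr_df["p_fdr"] = cohort.fdr_adjust(corr_df["p_value"].to_numpy())
    return {
        "comparison": comparison,
        "znormalized": znormed,
        "ranking": ranking,
        "classifier": report,
        "stage_comparisons": stages,
        "updrs_correlations": corr_df,
    }


def provenance_block(config: dict, seed: int) -> dict:
    """Config hash + seed + version, echoed into every output for reproducibility."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "package_version": __version__,
    }
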