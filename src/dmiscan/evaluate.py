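"""Sensitivity/specificity and error-rate harness for the DMI scan.

Operates on replicate scan tables produced by
:func:`dmiscan.scan.pairwise_scan` together with the true DMI architecture
of each replicate.  "Detection" of a truth pair means the candidate flag
(X(2) below threshold and D' < 0) at the exact true marker pair;
candidate flags elsewhere count as false positives, including at markers
merely linked to a DMI (the hitchhiking signal is deliberately scored as
error here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "wald_ci",
    "EvaluationRow",
    "sensitivity_specificity",
    "fp_tp_rates",
    "distance_profile",
]


def wald_ci(p_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """95% Wald interval p +- z*sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n <= 0:
        return (float("nan"), float("nan"))
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


@dataclass(frozen=True)
class EvaluationRow:
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    n_truth: int
    specificity: float
    specificity_ci: tuple[float, float]
    n_replicates: int


def _normalize_pair(pair) -> tuple[int, int]:
    a, b = int(pair[0]), int(pair[1])
    return (a, b) if a <= b else (b, a)


def _candidate_pairs(scan_df: pd.DataFrame) -> set[tuple[int, int]]:
    cand = scan_df[scan_df["candidate"].astype(bool)]
    return {
        _normalize_pair(t) for t in zip(cand["m1"].to_numpy(), cand["m2"].to_numpy())
    }


def sensitivity_specificity(
    replicate_scans, truth_pairs, neutral_pairs=None
) -> EvaluationRow:
    """Detection rates across replicates.

    ``truth_pairs``: per-replicate list of true DMI marker pairs (or one
    list applied to all replicates).  Sensitivity is the flagged fraction
    over all (replicate, truth pair) instances.  ``neutral_pairs`` names
    designated no-DMI pairs per replicate; specificity is 1 minus the
    fraction of replicates in which any of them is flagged.
    """
    n_rep = len(replicate_scans)
    if n_rep == 0:
        raise ValueError("no replicates")
    truths = _per_replicate(truth_pairs, n_rep)
    neutrals = _per_replicate(neutral_pairs, n_rep) if neutral_pairs is not None else None

    hits = 0
    n_truth = 0
    neutral_flagged = 0
    for r, scan_df in enumerate(replicate_scans):
        cands = _candidate_pairs(scan_df)
        for pair in truths[r]:
            n_truth += 1
            if _normalize_pair(pair) in cands:
                hits += 1
        if neutrals is not None:
            if any(_normalize_pair(p) in cands for p in neutrals[r]):
                neutral_flagged += 1
    sens = hits / n_truth if n_truth else float("nan")
    if neutrals is not None:
        spec = 1.0 - neutral_flagged / n_rep
        spec_ci = wald_ci(spec, n_rep)
    else:
        spec, spec_ci = float("nan"), (float("nan"), float("nan"))
    return EvaluationRow(
        sensitivity=sens,
        sensitivity_ci=wald_ci(sens, n_truth) if n_truth else (float("nan"),) * 2,
        n_truth=n_truth,
        specificity=spec,
        specificity_ci=spec_ci,
        n_replicates=n_rep,
    )


def _per_replicate(items, n_rep):
    """Broadcast a flat pair list to all replicates, or validate a
    per-replicate list of pair lists."""
    items = list(items)

    def is_pair(x):
        return (
            isinstance(x, (tuple, list))
            and len(x) == 2
            and isinstance(x[0], (int, np.integer))
        )

    if all(is_pair(x) for x in items):
        return [list(items)] * n_rep
    if len(items) != n_rep:
        raise ValueError("per-replicate pair lists do not match replicate count")
    return [list(x) for x in items]


def _pair_class(scan_df, dmi_chromosomes) -> np.ndarray:
    """'neutral' when neither marker is on a DMI chromosome, else 'dmi'."""
    dmi = set(map(str, dmi_chromosomes))
    on1 = scan_df["chrom1"].astype(str).isin(dmi).to_numpy()
    on2 = scan_df["chrom2"].astype(str).isin(dmi).to_numpy()
    return np.where(on1 | on2, "dmi", "neutral")


def fp_tp_rates(
    replicate_scans,
    truth_pairs,
    dmi_chromosomes,
    thresholds=(-0.005, -0.01, -0.015),
    resample_size: int = 2000,
    n_resample: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """False/true positive rates by chromosome class and X(2) threshold.

    A pair is "positive" at a threshold when usable, X(2) < threshold and
    D' < 0.  False-positive pairs are stratified into 'neutral' (both
    markers on neutral chromosomes) and 'dmi' (any marker on a DMI
    chromosome, true pairs excluded).  Confidence intervals resample
    ``resample_size`` pairs ``n_resample`` times from the pooled per-pair
    outcomes (2.5/97.5 percentiles).
    """
    n_rep = len(replicate_scans)
    truths = _per_replicate(truth_pairs, n_rep)
    dmi_chroms = _per_replicate_chroms(dmi_chromosomes, n_rep)
    rng = np.random.default_rng(seed)

    pooled = []
    for r, scan_df in enumerate(replicate_scans):
        df = scan_df[scan_df["usable"].astype(bool)].copy()
        truth_set = {_normalize_pair(p) for p in truths[r]}
        keys = [
            _normalize_pair(t) for t in zip(df["m1"].to_numpy(), df["m2"].to_numpy())
        ]
        df["is_truth"] = [k in truth_set for k in keys]
        df["klass"] = _pair_class(df, dmi_chroms[r])
        pooled.append(df[["X2", "Dprime", "is_truth", "klass"]])
    pool = pd.concat(pooled, ignore_index=True)

    rows = []
    for thr in thresholds:
        pos = (pool["X2"].to_numpy() < thr) & (pool["Dprime"].to_numpy() < 0)
        for klass in ("neutral", "dmi"):
            sel = (~pool["is_truth"].to_numpy()) & (pool["klass"].to_numpy() == klass)
            rows.append(
                _rate_row("false_positive", klass, thr, pos[sel], rng,
                          resample_size, n_resample)
            )
        sel = pool["is_truth"].to_numpy()
        rows.append(
            _rate_row("true_positive", "truth", thr, pos[sel], rng,
                      resample_size, n_resample)
        )
    return pd.DataFrame(rows)


def _per_replicate_chroms(dmi_chromosomes, n_rep):
    items = list(dmi_chromosomes)
    if items and isinstance(items[0], (list, tuple, set)):
        if len(items) != n_rep:
            raise ValueError("per-replicate chromosome lists do not match replicates")
        return [list(x) for x in items]
    return [items] * n_rep


def _rate_row(kind, klass, thr, outcomes, rng, resample_size, n_resample):
    n = len(outcomes)
    rate = float(outcomes.mean()) if n else float("nan")
    if n:
        draws = rng.choice(
            outcomes.astype(np.int8), size=(n_resample, min(resample_size, n))
        )
        means = draws.mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return {
        "kind": kind, "class": klass, "threshold": thr,
        "rate": rate, "ci_low": float(lo), "ci_high": float(hi), "n_pairs": n,
    }


def distance_profile(
    replicate_scans,
    truth_pairs,
    windows_cm=(1, 2, 5, 10, 20, 50),
) -> pd.DataFrame:
    """Candidate fraction among pairs spanning windows around true DMI loci.

    For each true pair (La, Lb) and window w, selects scan pairs with one
    marker within w cM of La (same chromosome) and the other within w cM
    of Lb, and computes the flagged fraction; the table reports medians
    across (replicate, truth pair) together with the genome-wide flagged
    fraction per replicate.  Scan tables must carry cm1/cm2 columns.
    """
    n_rep = len(replicate_scans)
    truths = _per_replicate(truth_pairs, n_rep)
    per_window: dict[float, list[float]] = {w: [] for w in windows_cm}
    global_fracs = []
    for r, scan_df in enumerate(replicate_scans):
        df = scan_df[scan_df["usable"].astype(bool)]
        if "cm1" not in df.columns:
            raise ValueError("distance_profile requires cm1/cm2 columns")
        cand = df["candidate"].to_numpy().astype(bool)
        global_fracs.append(float(cand.mean()) if len(df) else float("nan"))
        truth_meta = []
        for la, lb in truths[r]:
            ra = df[(df["m1"] == la) | (df["m2"] == la)]
            rb = df[(df["m1"] == lb) | (df["m2"] == lb)]
            # recover chromosome / cM of the truth loci from any row
            meta = {}
            for locus, sub in ((la, ra), (lb, rb)):
                if len(sub):
                    row = sub.iloc[0]
                    if row["m1"] == locus:
                        meta[locus] = (str(row["chrom1"]), float(row["cm1"]))
                    else:
                        meta[locus] = (str(row["chrom2"]), float(row["cm2"]))
            if la in meta and lb in meta:
                truth_meta.append((meta[la], meta[lb]))
        c1 = df["chrom1"].astype(str).to_numpy()
        c2 = df["chrom2"].astype(str).to_numpy()
        cm1 = df["cm1"].to_numpy()
        cm2 = df["cm2"].to_numpy()
        for (ca, cma), (cb, cmb) in truth_meta:
            w_arr = np.array(windows_cm)
            near_a_1 = (c1 == ca)[:, None] & (np.abs(cm1 - cma)[:, None] <= w_arr)
            near_b_2 = (c2 == cb)[:, None] & (np.abs(cm2 - cmb)[:, None] <= w_arr)
            near_a_2 = (c2 == ca)[:, None] & (np.abs(cm2 - cma)[:, None] <= w_arr)
            near_b_1 = (c1 == cb)[:, None] & (np.abs(cm1 - cmb)[:, None] <= w_arr)
            span = (near_a_1 & near_b_2) | (near_a_2 & near_b_1)
            for wi, w in enumerate(windows_cm):
                sel = span[:, wi]
                if sel.any():
                    per_window[w].append(float(cand[sel].mean()))
    rows = []
    for w in windows_cm:
        vals = per_window[w]
        rows.append(
            {
                "window_cm": w,
                "median_fraction": float(np.median(vals)) if vals else float("nan"),
                "n_profiles": len(vals),
            }
        )
    out = pd.DataFrame(rows)
    out["genomic_median_fraction"] = (
        float(np.nanmedian(global_fracs)) if global_fracs else float("nan")
    )
    return out
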