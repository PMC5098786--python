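"""Evaluation statistics: per-sample rank correlation and confusion metrics.

Two complementary views of agreement between an inferred functional table
and an observed (e.g. shotgun-metagenomic) one:

* :func:`spearman_per_sample` — Spearman's rank correlation of ortholog
  abundances, computed per shared sample over the union of features (an
  ortholog present in only one table counts as 0 in the other; an
  ``intersection`` mode restricts to shared features instead).

* :func:`confusion_metrics` — agreement of differential-abundance calls.
  The caller supplies two sets of significant ortholog IDs (produced by
  any external test at any threshold) over a common ortholog universe;
  true negatives are all orthologs in the universe flagged by neither
  side.  Balanced accuracy = TPR/2 + (1 - FPR)/2 summarizes the tradeoff.

* :func:`cutoff_sweep` — the full inference repeated across a grid of
  identity cutoffs, tabulating per-sample passed fraction, rank
  correlation, and ortholog detection counts per cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import nnsearch
from .infer import infer_ko_abundance, passed_fraction
from .refdb import ReferenceDatabase
from .tables import KoAbundanceTable, OtuTable

__all__ = [
    "SignificanceCallSet",
    "ConfusionMetrics",
    "PRESET_CUTOFFS",
    "spearman_per_sample",
    "summarize_rho",
    "confusion_metrics",
    "cutoff_sweep",
]

logger = logging.getLogger("koinfer.evaluate")

#: The ten identity cutoffs conventionally swept when tuning the method.
PRESET_CUTOFFS = (0.75, 0.80, 0.85, 0.90, 0.95, 0.96, 0.97, 0.98, 0.99, 1.0)


@dataclass(frozen=True)
class SignificanceCallSet:
    """Ortholog IDs flagged significant by an external differential test."""

    feature_ids: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        if len(self.feature_ids) > self.universe_size:
            raise ValueError(
                f"{len(self.feature_ids)} significant features exceed the "
                f"universe of {self.universe_size}"
            )

    @classmethod
    def from_file(cls, path, universe_size: int) -> "SignificanceCallSet":
        """Read one ortholog ID per line (blank lines and '#' comments skipped)."""
        ids = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    ids.add(line)
        return cls(feature_ids=frozenset(ids), universe_size=universe_size)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and rates over a fixed ortholog universe."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        """Sensitivity: TP / (TP + FN); 0 when no positives exist."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def fpr(self) -> float:
        """1 - specificity: FP / (FP + TN); 0 when no negatives exist."""
        denom = self.fp + self.tn
        return self.fp / denom if denom else 0.0

    @property
    def balanced_accuracy(self) -> float:
        return self.tpr / 2 + (1 - self.fpr) / 2

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": self.tpr, "fpr": self.fpr,
            "balanced_accuracy": self.balanced_accuracy,
        }


def confusion_metrics(
    inferred_sig: SignificanceCallSet,
    observed_sig: SignificanceCallSet,
) -> ConfusionMetrics:
    """Score inferred differential-abundance calls against observed ones.

    TP = called by both; FP = inferred only; FN = observed only; TN = the
    rest of the common ortholog universe.  The four counts partition the
    universe exactly.
    """
    if inferred_sig.universe_size != observed_sig.universe_size:
        raise ValueError(
            f"universe sizes differ: {inferred_sig.universe_size} vs "
            f"{observed_sig.universe_size}"
        )
    inf, obs = inferred_sig.feature_ids, observed_sig.feature_ids
    tp = len(inf & obs)
    fp = len(inf - obs)
    fn = len(obs - inf)
    tn = inferred_sig.universe_size - len(inf | obs)
    if tn < 0:
        raise ValueError("universe smaller than the union of call sets")
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def spearman_per_sample(
    inferred: KoAbundanceTable,
    observed: KoAbundanceTable,
    feature_space: str = "union",
) -> pd.Series:
    """Spearman's rho between inferred and observed abundances, per sample.

    Computed over shared samples.  ``feature_space='union'`` (default)
    joins the two feature sets with missing entries as 0, so features
    detected by only one side count against agreement; ``'intersection'``
    restricts to features present in both tables.  Ties receive average
    ranks.  A sample with fewer than 3 joint features is reported as NaN
    with a warning.
    """
    if feature_space not in {"union", "intersection"}:
        raise ValueError(f"unknown feature_space {feature_space!r}")
    shared = [s for s in inferred.sample_ids if s in set(observed.sample_ids)]
    if not shared:
        raise ValueError("no shared sample IDs between tables")
    if feature_space == "union":
        features = sorted(set(inferred.feature_ids) | set(observed.feature_ids))
    else:
        features = sorted(set(inferred.feature_ids) & set(observed.feature_ids))
    a = inferred.df.reindex(index=features, columns=shared, fill_value=0.0).fillna(0.0)
    b = observed.df.reindex(index=features, columns=shared, fill_value=0.0).fillna(0.0)
    rhos = {}
    for s in shared:
        if len(features) < 3:
            logger.warning(
                "event=spearman_undefined sample_id=%s n_features=%d", s, len(features)
            )
            rhos[s] = np.nan
            continue
        rho = stats.spearmanr(a[s].to_numpy(), b[s].to_numpy()).statistic
        rhos[s] = float(rho)
    return pd.Series(rhos, name="rho")


def summarize_rho(rhos: pd.Series) -> dict:
    """Five-number summary of per-sample correlations (box-plot statistics)."""
    clean = rhos.dropna()
    if clean.empty:
        return {"n": 0}
    q = np.percentile(clean.to_numpy(), [0, 25, 50, 75, 100])
    return {
        "n": int(clean.size),
        "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
    }


def cutoff_sweep(
    otus: OtuTable,
    rep_seqs: Mapping[str, str],
    db: ReferenceDatabase,
    cutoffs: Sequence[float] = PRESET_CUTOFFS,
    observed: KoAbundanceTable | None = None,
    search_rc: bool = False,
) -> pd.DataFrame:
    """Run the full inference at each identity cutoff and tabulate the results.

    One row per (cutoff, sample) with columns ``passed_fraction``,
    ``n_kos_sample`` (orthologs with A_K > 0 in that sample),
    ``n_kos_total`` (orthologs detected anywhere at that cutoff), and, when
    an observed table is given, ``rho`` (Spearman vs. observed).

    The per-OTU best identity does not depend on the cutoff, so the
    alignments run once and each cutoff only re-applies the keep/drop
    decision; this is exactly equivalent to re-searching per cutoff.
    """
    for c in cutoffs:
        if not 0.0 < c <= 1.0:
            raise ValueError(f"cutoff {c} outside (0, 1]")
    base = nnsearch.best_hits(rep_seqs, db, search_rc=search_rc)
    rows = []
    for cutoff in cutoffs:
        hits = nnsearch.apply_cutoff(base, cutoff)
        frac = passed_fraction(otus, hits)
        ko_table = infer_ko_abundance(otus, hits, db)
        detected = ko_table.df.to_numpy() > 0
        n_total = int(detected.any(axis=1).sum())
        per_sample_kos = pd.Series(
            detected.sum(axis=0), index=ko_table.sample_ids
        )
        rho = (
            spearman_per_sample(ko_table, observed)
            if observed is not None and len(ko_table.df)
            else None
        )
        for s in otus.sample_ids:
            row = {
                "cutoff": cutoff,
                "sample_id": s,
                "passed_fraction": float(frac[s]),
                "n_kos_sample": int(per_sample_kos.get(s, 0)),
                "n_kos_total": n_total,
            }
            if observed is not None:
                row["rho"] = float(rho[s]) if rho is not None and s in rho else np.nan
            rows.append(row)
        logger.info(
            "event=sweep_point cutoff=%g n_passing_otus=%d n_kos_total=%d",
            cutoff, len(hits), n_total,
        )
    return pd.DataFrame(rows)
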