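"""Maximum-likelihood mindset classification of play records.

Each record is scored under both mindset models by summing the log softmax
probability of every recorded action given its recorded state. The noise
level beta is unknown at classification time and is treated as a nuisance
parameter: the log likelihood is maximized over a log-spaced beta grid per
model (profile likelihood). An "oracle beta" mode that evaluates at the
generating beta is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mdp import QTable
from .simulation import PlayRecord
from .water_task import STATE_SPACE

__all__ = [
    "ClassificationResult",
    "default_beta_grid",
    "profile_log_likelihood",
    "classify_record",
    "classify_records",
    "confusion_matrix",
    "accuracy_by_beta",
]


def default_beta_grid() -> np.ndarray:
    """Log-spaced beta grid: log beta from -2.5 to 2.5 in steps of 0.125."""
    return np.exp(np.arange(-2.5, 2.5 + 1e-9, 0.125))


@dataclass(frozen=True)
class ClassificationResult:
    record_id: str
    player_id: str
    true_mindset: str
    beta_true: float
    loglik_fixed: float
    loglik_malleable: float
    beta_hat_fixed: float
    beta_hat_malleable: float
    predicted: str
    tie: bool = False

    @property
    def correct(self) -> bool:
        return self.predicted == self.true_mindset


def _step_pairs(record: PlayRecord) -> list[tuple[int, int]]:
    return [
        (STATE_SPACE.encode(s.state_before.as_tuple()), int(s.action))
        for s in record.steps
    ]


def profile_log_likelihood(
    pairs: Sequence[tuple[int, int]], q: QTable, beta_grid: np.ndarray
) -> np.ndarray:
    """Log likelihood of an action sequence at every beta on the grid.

    Vectorized over the grid: for each step the log softmax probability of
    the taken action (restricted to the actions available in that state)
    is evaluated at all betas and summed.
    """
    betas = np.asarray(beta_grid, dtype=float)
    if betas.size == 0:
        raise ValueError("beta grid is empty")
    total = np.zeros_like(betas)
    for s, a in pairs:
        avail = np.nonzero(q.available[s])[0]
        if a not in avail:
            return np.full_like(betas, -np.inf)
        qs = q.values[s, avail]
        z = betas[:, None] * qs[None, :]
        z -= z.max(axis=1, keepdims=True)
        logp = z[:, avail == a].ravel() - np.log(np.exp(z).sum(axis=1))
        total += logp
    return total


def classify_record(
    record: PlayRecord,
    q_fixed: QTable,
    q_malleable: QTable,
    beta_grid: np.ndarray | None = None,
    oracle_beta: bool = False,
) -> ClassificationResult:
    """Classify one record as fixed or malleable.

    Per model the likelihood is maximized over the beta grid (or evaluated
    at the generating beta when ``oracle_beta``). The larger maximized log
    likelihood wins; exact ties go to fixed and are flagged.
    """
    grid = (
        np.array([record.beta])
        if oracle_beta
        else (default_beta_grid() if beta_grid is None else np.asarray(beta_grid))
    )
    pairs = _step_pairs(record)
    ll_f = profile_log_likelihood(pairs, q_fixed, grid)
    ll_m = profile_log_likelihood(pairs, q_malleable, grid)
    best_f, best_m = float(ll_f.max()), float(ll_m.max())
    if np.isneginf(best_f) and np.isneginf(best_m):
        raise ValueError(
            f"record {record.player_id}/{record.run_index} has zero likelihood "
            "under both models (unclassifiable)"
        )
    tie = best_f == best_m
    predicted = "fixed" if best_f >= best_m else "malleable"
    return ClassificationResult(
        record_id=f"{record.player_id}/{record.run_index}",
        player_id=record.player_id,
        true_mindset=record.mindset,
        beta_true=record.beta,
        loglik_fixed=best_f,
        loglik_malleable=best_m,
        beta_hat_fixed=float(grid[int(np.argmax(ll_f))]) if np.isfinite(best_f) else np.nan,
        beta_hat_malleable=float(grid[int(np.argmax(ll_m))]) if np.isfinite(best_m) else np.nan,
        predicted=predicted,
        tie=tie,
    )


def classify_records(
    records: Iterable[PlayRecord],
    q_fixed: QTable,
    q_malleable: QTable,
    beta_grid: np.ndarray | None = None,
    oracle_beta: bool = False,
) -> list[ClassificationResult]:
    grid = default_beta_grid() if beta_grid is None else np.asarray(beta_grid)
    return [
        classify_record(r, q_fixed, q_malleable, grid, oracle_beta=oracle_beta)
        for r in records
    ]


def confusion_matrix(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    """Row-normalized 2x2 confusion matrix (rows: generating model)."""
    counts = pd.DataFrame(
        0.0, index=["fixed", "malleable"], columns=["fixed", "malleable"]
    )
    for r in results:
        counts.loc[r.true_mindset, r.predicted] += 1
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        missing = row_sums[row_sums == 0].index.tolist()
        raise ValueError(f"no records for generating model(s): {missing}")
    return counts.div(row_sums, axis=0)


def accuracy_by_beta(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    """Per-player classification accuracy vs log(beta), sorted by log(beta).

    Returns columns: player_id, mindset, log_beta, n_records, accuracy.
    """
    rows: dict[str, dict] = {}
    for r in results:
        row = rows.setdefault(
            r.player_id,
            {
                "player_id": r.player_id,
                "mindset": r.true_mindset,
                "log_beta": float(np.log(r.beta_true)),
                "n_records": 0,
                "n_correct": 0,
            },
        )
        row["n_records"] += 1
        row["n_correct"] += int(r.correct)
    df = pd.DataFrame(rows.values())
    df["accuracy"] = df["n_correct"] / df["n_records"]
    return df.sort_values("log_beta", ignore_index=True)


def accuracy_beta_correlation(results: Iterable[ClassificationResult], mindset: str):
    """Spearman rank correlation of per-player accuracy with log(beta)."""
    df = accuracy_by_beta(results)
    df = df[df["mindset"] == mindset]
    rho, p = stats.spearmanr(df["log_beta"], df["accuracy"])
    return float(rho), float(p)
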