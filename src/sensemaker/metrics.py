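"""Scoring and bias metrics.

Negentropy (normalized negative entropy) measures certainty on a 0-100%
scale: N = 100 * (E_max - E) / E_max with E the Shannon entropy in bits
and E_max = 2 for four hypotheses (1 for two).  KL divergence K (bits)
and the similarity score S = 100 * 2^-K compare two distributions; the
relative success rate RSR rescales S against a uniform null model, and
the relative match rate RMR compares a model's chosen sequence frequency
to the modal sequence.  Bias direction is read off the negentropy gap:
an agent *less* certain than the normative solver on the same evidence is
anchoring (under-adjustment); *more* certain is confirmation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import ProbDist

__all__ = [
    "negentropy",
    "kl_divergence",
    "similarity",
    "rsr",
    "rmr",
    "s1_score",
    "s2_score",
    "bias_label",
    "response_frame",
    "summarize",
    "PROB_FLOOR",
]

# Zero probabilities are floored before logs: the response interface only
# admits 1-99% anyway, and the floor keeps K finite.
PROB_FLOOR = 1e-6


def _floored(p: np.ndarray) -> np.ndarray:
    q = np.maximum(np.asarray(p, dtype=float), PROB_FLOOR)
    return q / q.sum()


def negentropy(dist: ProbDist) -> float:
    """N = 100 * (E_max - E) / E_max, percent; 0 = uniform, 100 = certain."""
    e_max = math.log2(len(dist.probs))
    return 100.0 * (e_max - dist.entropy()) / e_max


def kl_divergence(p: ProbDist, m: ProbDist) -> float:
    """K(P||M) in bits, with zero-probability flooring on both arguments."""
    if p.labels != m.labels:
        raise ValueError("distributions must share labels")
    pp, mm = _floored(p.probs), _floored(m.probs)
    return float(np.sum(pp * np.log2(pp / mm)))


def similarity(k: float) -> float:
    """S = 100 * 2^-K percent; 100 when identical, toward 0 as K grows."""
    return 100.0 * 2.0 ** (-k)


def s1_score(normative: ProbDist, dist: ProbDist) -> float:
    """Similarity of a response to the normative reference distribution."""
    return similarity(kl_divergence(normative, dist))


def rsr(s_pm: float, s_pr: float) -> float:
    """Relative success rate: (S_PM - S_PR) / (100 - S_PR), percent.

    Floored at zero when the candidate does no better than the null
    model; NaN at the S_PR = 100 singularity (the null model already
    predicts perfectly).
    """
    if s_pr >= 100.0:
        return float("nan")
    return max(0.0, 100.0 * (s_pm - s_pr) / (100.0 - s_pr))


def rmr(freq_model_seq: float, freq_modal_seq: float) -> float:
    """Relative match rate: model sequence frequency over modal frequency."""
    if freq_modal_seq <= 0:
        raise ValueError("modal sequence frequency must be positive")
    return 100.0 * freq_model_seq / freq_modal_seq


def s2_score(allocation: Sequence[float], truth: str, labels: Sequence[str]) -> float:
    """The percentage of resources allocated to the ground-truth category."""
    alloc = np.asarray(allocation, dtype=float)
    if abs(alloc.sum() - 100.0) > 1e-6:
        raise ValueError("allocation must sum to 100")
    if truth not in labels:
        raise ValueError(f"unknown truth label {truth!r}")
    return float(alloc[list(labels).index(truth)])


def bias_label(n_agent: float, n_norm: float, tol: float = 1e-9) -> str:
    """confirmation if the agent is more certain than the norm, anchoring
    if less, none within tolerance."""
    if n_agent > n_norm + tol:
        return "confirmation"
    if n_agent < n_norm - tol:
        return "anchoring"
    return "none"


# ---------------------------------------------------------------------------
# Aggregation over trial records
# ---------------------------------------------------------------------------


def response_frame(records, subject: int = 0) -> pd.DataFrame:
    """One row per response point: probabilities, negentropies, S1, bias.

    ``records`` is an iterable of TrialRecords (one subject's run or many,
    tagged by ``subject``).
    """
    rows = []
    for rec in records:
        for stage_idx, rp in enumerate(rec.responses):
            n_m, n_q = negentropy(rp.agent), negentropy(rp.normative)
            row = {
                "subject": subject,
                "task": rec.task_id,
                "trial": rec.trial_index,
                "stage_index": stage_idx,
                "stage": rp.stage,
                "truth": rec.ground_truth,
                "N_model": n_m,
                "N_bayes": n_q,
                "S1": s1_score(rp.normative, rp.agent),
                "bias": bias_label(n_m, n_q),
            }
            for lbl, p in rp.agent.as_dict().items():
                row[f"p_model_{lbl}"] = p
            for lbl, p in rp.normative.as_dict().items():
                row[f"p_bayes_{lbl}"] = p
            if rec.allocation is not None and stage_idx == len(rec.responses) - 1:
                row["S2"] = s2_score(rec.allocation, rec.ground_truth, rec.labels)
                for lbl, a in zip(rec.labels, rec.allocation):
                    row[f"alloc_{lbl}"] = int(a)
                row["lead_prob"] = float(np.max(rp.agent.probs))
                row["lead_alloc"] = float(rec.allocation[int(np.argmax(rp.agent.probs))])
            if rec.layer_sequence:
                row["layer_sequence"] = "-".join(rec.layer_sequence)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize(frame: pd.DataFrame) -> dict:
    """Per-task means of S1/S2/negentropies and bias-label counts."""
    out: dict[str, dict] = {}
    for task, g in frame.groupby("task"):
        final = g[g["S2"].notna()] if "S2" in g else g.iloc[0:0]
        out[f"task{task}"] = {
            "mean_S1": float(g["S1"].mean()),
            "mean_S2": float(final["S2"].mean()) if len(final) else None,
            "mean_N_model": float(g["N_model"].mean()),
            "mean_N_bayes": float(g["N_bayes"].mean()),
            "bias_counts": {k: int(v) for k, v in g["bias"].value_counts().items()},
        }
    return out
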