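"""Twin transform, four-class labels and the fused binary decision.

Each source patch is expanded into a plus branch (identity) and a minus
branch (horizontal mirror) — an involutive, label-preserving pair chosen
because the source material never specifies the two transforms.  Binary
labels {P, N} become four classes {P+, P-, N+, N-} according to branch.
The two branch posteriors are fused back to a binary decision:

* both branches agree on their own negative class -> N;
* both agree on their own positive class -> P;
* otherwise the larger of the two group maxima wins (N on a strict win of
  the N group, P otherwise — the published rule's self-comparison is an
  evident typo, resolved this way to stay consistent with its stated
  "otherwise P" fallback).

Confidence is ``m_win / (m_P + m_N)`` where ``m_P``/``m_N`` are the group
maxima over both branch posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FOUR_CLASSES = ("P+", "P-", "N+", "N-")
_IDX = {name: i for i, name in enumerate(FOUR_CLASSES)}


@dataclass(frozen=True)
class TwinPair:
    """Plus/minus branch views of one source patch."""

    x_plus: np.ndarray
    x_minus: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.x_plus.shape != self.x_minus.shape:
            raise ValueError("branch shapes must match the source shape")


@dataclass(frozen=True)
class FourClassPosterior:
    """Probabilities over (P+, P-, N+, N-)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("posterior must have exactly 4 entries")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError("posterior must sum to 1 within 1e-9")


@dataclass(frozen=True)
class FusedDecision:
    label: str  # "P" | "N"
    confidence: float
    rule_branch: str  # "agree_negative" | "agree_positive" | "group_max"


def twin_transform(x: np.ndarray, source_id: str = "") -> TwinPair:
    """Identity / horizontal-mirror branch pair for a 2-D (or HxWxC) patch."""
    arr = np.asarray(x)
    if arr.ndim < 2 or arr.size == 0:
        raise ValueError("input must be a non-empty 2-D (or deeper) array")
    return TwinPair(
        x_plus=arr.copy(), x_minus=np.flip(arr, axis=1).copy(),
        source_id=source_id,
    )


def map_to_four_class(label: str, branch: str) -> str:
    """(P|N, plus|minus) -> one of P+, P-, N+, N-."""
    if label not in ("P", "N"):
        raise ValueError(f"label must be 'P' or 'N', got {label!r}")
    if branch not in ("plus", "minus"):
        raise ValueError(f"branch must be 'plus' or 'minus', got {branch!r}")
    return label + ("+" if branch == "plus" else "-")


def fuse_twin_posteriors(
    theta: FourClassPosterior | np.ndarray,
    psi: FourClassPosterior | np.ndarray,
) -> FusedDecision:
    """Fuse the plus-branch (theta) and minus-branch (psi) posteriors."""
    t = _as_posterior(theta).probs
    s = _as_posterior(psi).probs
    y_plus = int(np.argmax(t))
    y_minus = int(np.argmax(s))

    m_p = max(t[_IDX["P+"]], t[_IDX["P-"]], s[_IDX["P+"]], s[_IDX["P-"]])
    m_n = max(t[_IDX["N+"]], t[_IDX["N-"]], s[_IDX["N+"]], s[_IDX["N-"]])

    if y_plus == _IDX["N+"] and y_minus == _IDX["N-"]:
        label, branch = "N", "agree_negative"
    elif y_plus == _IDX["P+"] and y_minus == _IDX["P-"]:
        label, branch = "P", "agree_positive"
    else:
        label = "N" if m_n > m_p else "P"  # ties go to P
        branch = "group_max"

    m_win = m_n if label == "N" else m_p
    denom = m_p + m_n
    confidence = float(m_win / denom) if denom > 0 else 0.5
    return FusedDecision(label=label, confidence=confidence, rule_branch=branch)


def _as_posterior(p) -> FourClassPosterior:
    if isinstance(p, FourClassPosterior):
        return p
    return FourClassPosterior(probs=np.asarray(p, dtype=float))
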