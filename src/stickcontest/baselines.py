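"""Asocial anchor-and-adjust belief-updating baselines.

Anchor-and-adjust (AA) models explain belief revision without any
reasoning about the information source: the listener compares the
strength of new evidence against a reference point ``R`` and shifts
their belief additively, ``P(w|u) = P(w) + eta * (s(u) - R)``.

In the simplest variant the anchor is neutral (``R = 0``) and the
adjustment weight fixed (``eta = 0.5``).  The *minimum acceptable
strength* (MAS) variant frees the reference point, so positive evidence
that falls short of ``R`` is treated as if it were negative -- an
asocial route to the weak evidence effect that, unlike the pragmatic
account, predicts no relationship with speaker expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import LENGTHS, MIDPOINT

__all__ = ["AAParams", "evidence_strength", "aa_update"]


@dataclass(frozen=True)
class AAParams:
    """Adjustment weight ``eta`` in [0, 1] and reference point ``anchor`` in [-1, 1].

    The simple AA variant fixes ``eta = 0.5, anchor = 0``; the MAS
    variant treats the anchor (and here also ``eta``) as free.
    """

    eta: float = 0.5
    anchor: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if not (-1.0 <= self.anchor <= 1.0):
            raise ValueError("anchor must lie in [-1, 1]")


def evidence_strength(u: int) -> float:
    """Signed strength of a stick of length ``u``, oriented toward "longer".

    Linear map of the length onto [-1, 1]: s(u) = (u - 5) / 4, so the
    midpoint is neutral, 9" is maximal evidence for longer and 1" is
    maximal evidence for shorter.  One scale serves both contestants.
    """
    if u not in LENGTHS:
        raise ValueError(f"utterance must be an integer length in [1, 9], got {u!r}")
    return (u - MIDPOINT) / (max(LENGTHS) - MIDPOINT)


def aa_update(prior: float, u: int, params: AAParams = AAParams()) -> float:
    """Anchor-and-adjust belief update, clipped to the probability scale.

    Returns ``prior + eta * (s(u) - R)`` clipped to [0, 1].  The belief
    is P(longer); evidence below the anchor moves it down even when the
    evidence nominally favours longer.
    """
    if not (0.0 <= prior <= 1.0):
        raise ValueError("prior must lie in [0, 1]")
    updated = prior + params.eta * (evidence_strength(u) - params.anchor)
    return min(1.0, max(0.0, updated))
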