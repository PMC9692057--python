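"""Exact listener and speaker models on the Stick Contest state space.

The Stick Contest is a persuasion game: a judge must decide whether the
average length of five hidden sticks (integer lengths between 1" and 9",
all distinct) exceeds the 5" midpoint.  Two contestants each hold an
*agenda* -- one is rewarded for a "longer" verdict, the other for
"shorter" -- and each may reveal exactly one of the five actual sticks as
evidence.

This module implements, by full enumeration over the 126 possible worlds
(5-element subsets of {1..9}):

* the *literal listener* ``L0``, who conditions only on the revealed
  stick being one of the five,
* a *motivated speaker* whose utility combines truthfulness (they can
  only show actual sticks, so the epistemic term is constant) with a
  persuasive term weighted by a bias ``beta``, and
* the *pragmatic listener* ``L1``, who inverts the speaker model and may
  therefore *discount* weak favourable evidence: if a strongly biased
  contestant shows a 6" stick, that is evidence no longer stick exists.

The soft-max temperature ``alpha`` multiplies ``beta`` everywhere in
this task, so their product is treated as the single free parameter
``beta`` (``alpha`` is fixed to 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "LENGTHS",
    "N_STICKS",
    "MIDPOINT",
    "AGENDAS",
    "World",
    "VerdictBelief",
    "SpeakerParams",
    "enumerate_worlds",
    "verdict_of",
    "literal_listener",
    "persuasive_utility",
    "speaker_distribution",
    "pragmatic_listener",
    "weak_evidence_effect",
    "effect_size",
    "simulation_grid",
]

#: Admissible stick lengths (inches).
LENGTHS = tuple(range(1, 10))
#: Number of hidden sticks in a world.
N_STICKS = 5
#: The verdict midpoint (inches).
MIDPOINT = 5.0
#: The two possible agendas / verdicts.
AGENDAS = ("longer", "shorter")


def _check_agenda(agenda: str) -> str:
    if agenda not in AGENDAS:
        raise ValueError(f"agenda must be one of {AGENDAS}, got {agenda!r}")
    return agenda


def _check_utterance(u: int) -> int:
    if u not in LENGTHS:
        raise ValueError(f"utterance must be an integer length in [1, 9], got {u!r}")
    return int(u)


@dataclass(frozen=True)
class World:
    """A hidden set of five distinct stick lengths (inches), stored sorted."""

    sticks: tuple

    def __post_init__(self):
        sticks = tuple(sorted(int(s) for s in self.sticks))
        if len(sticks) != N_STICKS:
            raise ValueError(f"a world has exactly {N_STICKS} sticks, got {len(sticks)}")
        if any(s not in LENGTHS for s in sticks):
            raise ValueError("stick lengths must be integers in [1, 9]")
        if len(set(sticks)) != N_STICKS:
            raise ValueError("stick lengths must be distinct")
        object.__setattr__(self, "sticks", sticks)

    def __contains__(self, u: int) -> bool:
        return u in self.sticks

    @property
    def mean(self) -> float:
        return sum(self.sticks) / N_STICKS


@dataclass(frozen=True)
class VerdictBelief:
    """Probability mass over the binary verdict {longer, shorter}."""

    p_longer: float
    p_shorter: float

    def __post_init__(self):
        if not (0.0 <= self.p_longer <= 1.0 and 0.0 <= self.p_shorter <= 1.0):
            raise ValueError("belief components must lie in [0, 1]")
        if abs(self.p_longer + self.p_shorter - 1.0) > 1e-12:
            raise ValueError("belief must sum to 1 within 1e-12")

    def p(self, agenda: str) -> float:
        """Probability assigned to ``agenda``."""
        return self.p_longer if _check_agenda(agenda) == "longer" else self.p_shorter


@dataclass(frozen=True)
class SpeakerParams:
    """Free parameters of the motivated speaker.

    ``beta`` weights the persuasive term of the speaker utility;
    ``beta = 0`` recovers an unbiased speaker who reveals a stick
    uniformly at random, in which case the pragmatic listener reduces
    exactly to the literal listener.  ``epsilon`` is the semantic noise
    floor of the literal listener; in this task the speaker can only
    reveal actual sticks, so it is fixed to 0 and exists for generality.
    """

    beta: float
    epsilon: float = 0.0

    def __post_init__(self):
        if not self.beta >= 0:
            raise ValueError("beta must be nonnegative")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must lie in [0, 1)")


# ---------------------------------------------------------------------------
# World enumeration (cached module-level tables)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _tables():
    """Enumerated worlds and derived lookup tables.

    Returns (worlds, verdicts, contains, l0_longer) where

    * ``worlds``   : (126, 5) int array, lexicographic order,
    * ``verdicts`` : (126,) int array, +1 longer / -1 shorter / 0 tie,
    * ``contains`` : (9, 126) bool, contains[u-1, w] == (u in world w),
    * ``l0_longer``: (9,) float, literal-listener P(longer | u).
    """
    worlds = np.array(list(itertools.combinations(LENGTHS, N_STICKS)), dtype=np.int64)
    sums = worlds.sum(axis=1)
    target = int(MIDPOINT * N_STICKS)
    verdicts = np.where(sums > target, 1, np.where(sums < target, -1, 0))
    contains = np.stack([(worlds == u).any(axis=1) for u in LENGTHS])
    longer = (contains & (verdicts == 1)).sum(axis=1)
    shorter = (contains & (verdicts == -1)).sum(axis=1)
    l0_longer = longer / (longer + shorter)
    for arr in (worlds, verdicts, contains, l0_longer):
        arr.setflags(write=False)
    return worlds, verdicts, contains, l0_longer


def enumerate_worlds():
    """All possible worlds with their (uniform) prior weights.

    Returns
    -------
    worlds : ndarray of shape (126, 5)
        Every 5-element subset of {1..9} as a sorted row, in
        lexicographic order.
    weights : ndarray of shape (126,)
        Uniform prior weights summing to 1.
    """
    worlds = _tables()[0]
    weights = np.full(len(worlds), 1.0 / len(worlds))
    return worlds, weights


def verdict_of(w) -> str:
    """Ground-truth verdict of a world: mean above/below/at the midpoint."""
    sticks = w.sticks if isinstance(w, World) else World(tuple(w)).sticks
    mean = sum(sticks) / N_STICKS
    if mean > MIDPOINT:
        return "longer"
    if mean < MIDPOINT:
        return "shorter"
    return "tie"


# ---------------------------------------------------------------------------
# Listeners and speaker
# ---------------------------------------------------------------------------

def _l0_p_longer(u: int, epsilon: float = 0.0) -> float:
    """Literal-listener P(longer | u), with optional semantic noise floor."""
    _, verdicts, contains, _ = _tables()
    if epsilon == 0.0:
        return float(_tables()[3][u - 1])
    lik = np.where(contains[u - 1], 1.0, epsilon)
    longer = lik[verdicts == 1].sum()
    shorter = lik[verdicts == -1].sum()
    return float(longer / (longer + shorter))


def literal_listener(u: int, epsilon: float = 0.0) -> VerdictBelief:
    """Belief of the literal listener after seeing a stick of length ``u``.

    Conditions the uniform world prior on ``u`` being one of the five
    hidden sticks and marginalises the verdict, excluding exact-tie
    worlds so that the prior over {longer, shorter} is exactly 0.5/0.5.
    """
    _check_utterance(u)
    p = _l0_p_longer(u, epsilon)
    return VerdictBelief(p_longer=p, p_shorter=1.0 - p)


def persuasive_utility(u: int, agenda: str) -> float:
    """Persuasive utility of showing ``u`` under the given agenda.

    The log-probability the literal listener assigns to the agenda
    after seeing ``u``: ``ln L0(agenda | u)``.  Strictly increasing in
    ``u`` for the longer agenda and strictly decreasing for shorter.
    """
    _check_utterance(u)
    p = literal_listener(u).p(agenda)
    if p == 0.0:
        raise ValueError(
            f"degenerate semantics: literal listener assigns zero mass to {agenda!r} after u={u}"
        )
    return float(np.log(p))


def speaker_distribution(w, agenda: str, params: SpeakerParams) -> Dict[int, float]:
    """Choice distribution of a motivated speaker over the world's sticks.

    The speaker can only reveal one of the five actual sticks (so the
    epistemic utility term is constant) and soft-maxes the persuasive
    utility: ``P(u) \\propto L0(agenda | u)**beta``.  At ``beta = 0``
    the distribution is uniform over the five sticks; as ``beta`` grows
    it concentrates on the single strongest piece of evidence.
    """
    world = w if isinstance(w, World) else World(tuple(w))
    _check_agenda(agenda)
    logits = np.array(
        [params.beta * np.log(literal_listener(u, params.epsilon).p(agenda)) for u in world.sticks]
    )
    logits -= logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()
    return dict(zip(world.sticks, probs.tolist()))


def _pragmatic_p_longer_all(agenda: str, beta: float) -> np.ndarray:
    """Pragmatic-listener P(longer | u) for all nine utterances at once.

    Inverts the motivated speaker over all 126 worlds:
    ``P_L1(w | u) \\propto S(u | w, agenda, beta) P(w)`` restricted to
    worlds containing ``u``, then marginalises the verdict with the same
    tie exclusion as the literal listener.
    """
    worlds, verdicts, contains, l0_longer = _tables()
    la = l0_longer if agenda == "longer" else 1.0 - l0_longer
    logt = beta * np.log(la)  # (9,)
    # log normaliser of the speaker soft-max in each world
    logtw = logt[worlds - 1]  # (126, 5)
    logz = np.logaddexp.reduce(logtw, axis=1)  # (126,)
    # log speaker probability of uttering u in world w (-inf when u not
    # in w); the verdict marginal is assembled fully in log space so
    # that extreme biases (e.g. beta = 1e6) never underflow
    expo = np.where(contains, logt[:, None] - logz[None, :], -np.inf)  # (9, 126)
    with np.errstate(invalid="ignore"):
        lse_longer = special.logsumexp(expo[:, verdicts == 1], axis=1)
        lse_shorter = special.logsumexp(expo[:, verdicts == -1], axis=1)
    return special.expit(lse_longer - lse_shorter)


def pragmatic_listener(u: int, agenda: str, params: SpeakerParams) -> VerdictBelief:
    """Belief of the skeptical pragmatic listener.

    The listener knows the revealing contestant's agenda and perceived
    bias ``beta`` and inverts the speaker model by exact enumeration.
    With ``beta = 0`` this equals :func:`literal_listener` exactly.
    """
    _check_utterance(u)
    _check_agenda(agenda)
    p_longer = float(_pragmatic_p_longer_all(agenda, params.beta)[u - 1])
    return VerdictBelief(p_longer=p_longer, p_shorter=1.0 - p_longer)


def weak_evidence_effect(prior: float, posterior: float) -> float:
    """Size of the weak evidence effect: prior belief minus posterior belief.

    Positive values mean the evidence *backfired* -- belief in the
    proposition decreased despite evidence in its favour.  E.g. a drop
    from a prior of 0.5 to a posterior of 0.4 is an effect of 0.1.
    """
    return prior - posterior


def effect_size(u: int, agenda: str, params: SpeakerParams) -> float:
    """Weak evidence effect of showing ``u`` in support of ``agenda``.

    ``u`` must actually favour the agenda (u > 5 for longer, u < 5 for
    shorter).  Returns the prior belief in the agenda (0.5 by symmetry)
    minus the pragmatic listener's posterior belief in it.
    """
    _check_utterance(u)
    _check_agenda(agenda)
    supports = (u > MIDPOINT) if agenda == "longer" else (u < MIDPOINT)
    if not supports:
        raise ValueError(f"unsupported evidence: u={u} does not favour agenda {agenda!r}")
    posterior = pragmatic_listener(u, agenda, params).p(agenda)
    return weak_evidence_effect(0.5, posterior)


def simulation_grid(
    beta_values: Iterable[float],
    utterances: Iterable[int],
) -> pd.DataFrame:
    """Effect-size table over the cross product of ``beta`` and evidence.

    The agenda is implied by the evidence (longer for u > 5, shorter for
    u < 5; u = 5 supports neither and is rejected).  Returns a tidy
    frame with columns ``beta, utterance, agenda, effect_size``.  The
    set of utterances with a positive effect is nondecreasing (by
    inclusion) in ``beta``.
    """
    betas = list(beta_values)
    us = [_check_utterance(u) for u in utterances]
    if not betas or not us:
        raise ValueError("beta and utterance grids must be nonempty")
    rows = []
    for beta in betas:
        params = SpeakerParams(beta=float(beta))
        for u in us:
            agenda = "longer" if u > MIDPOINT else "shorter"
            rows.append(
                {
                    "beta": float(beta),
                    "utterance": u,
                    "agenda": agenda,
                    "effect_size": effect_size(u, agenda, params),
                }
            )
    return pd.DataFrame(rows, columns=["beta", "utterance", "agenda", "effect_size"])
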