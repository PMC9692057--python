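"""Synthetic participants with the Stick Contest experiment's structure.

The generator emulates the two-phase design: a *speaker expectation*
phase, where each participant ranks the example sticks {2, 4, 7, 8, 9}
by how likely the first contestant is to show them, and a *listener
judgment* phase, where they see one piece of evidence and report a
0-100 slider belief that the hidden sticks average longer than 5".

Participants come in two types.  A *pragmatic* participant expects
contestants to lead with their most persuasive stick (9 for the
long-biased contestant, 2 for the short-biased one) and updates like
the skeptical pragmatic listener at the generating bias ``beta_true``.
A *literal* ("hedging") participant expects a weaker stick to be shown
first and takes evidence at face value.  Contestant order is
counterbalanced exactly 50/50 and held constant across phases, and the
weak evidence values {4, 6} are oversampled, since they carry the
theoretically critical conditions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import SpeakerParams, literal_listener, persuasive_utility, pragmatic_listener
from .response import (
    EXAMPLE_STICKS,
    STRONGEST,
    ParticipantRecord,
    ResponseParams,
    predicted_slider,
    records_to_frame,
)

__all__ = [
    "GeneratorConfig",
    "sample_design",
    "simulate_speaker_phase",
    "simulate_listener_phase",
    "generate_records",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

#: Evidence values the first contestant can show, per contestant order,
#: with default sampling weights oversampling the weak values {4, 6}.
DEFAULT_CONDITION_WEIGHTS: Dict[int, float] = {
    1: 1.0, 2: 1.0, 3: 1.0, 4: 3.0, 6: 3.0, 7: 1.0, 8: 1.0, 9: 1.0,
}

_EVIDENCE_SETS = {"longer": (6, 7, 8, 9), "shorter": (4, 3, 2, 1)}

#: Hedging policies: where a literal participant's rank-1 stick comes from.
HEDGING_POLICIES = ("interior", "non-strongest", "uniform")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 723 participants (post-exclusion counts), 67% of
    them pragmatic types, a generating persuasive bias of 2.26, a
    response offset of -0.13 with 0.1 response noise (probability
    scale), and weak evidence oversampled 3:1.
    """

    n_participants: int = 723
    p_pragmatic: float = 0.67
    beta_true: float = 2.26
    response: ResponseParams = field(default_factory=lambda: ResponseParams(offset=-0.13, noise_sd=0.1))
    condition_weights: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_WEIGHTS)
    )
    hedging: str = "interior"
    seed: int = 1

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be nonnegative")
        if not (0.0 <= self.p_pragmatic <= 1.0):
            raise ValueError("p_pragmatic must lie in [0, 1]")
        if not self.beta_true >= 0:
            raise ValueError("beta_true must be nonnegative")
        weights = self.condition_weights
        if any(w < 0 for w in weights.values()) or not any(w > 0 for w in weights.values()):
            raise ValueError("condition weights must be nonnegative and not all zero")
        if self.hedging not in HEDGING_POLICIES:
            raise ValueError(f"hedging must be one of {HEDGING_POLICIES}")

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "p_pragmatic": self.p_pragmatic,
            "beta_true": self.beta_true,
            "response": {"offset": self.response.offset, "noise_sd": self.response.noise_sd},
            "condition_weights": {str(k): v for k, v in self.condition_weights.items()},
            "hedging": self.hedging,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        if "response" in data:
            data["response"] = ResponseParams(**data["response"])
        if "condition_weights" in data:
            data["condition_weights"] = {int(k): float(v) for k, v in data["condition_weights"].items()}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def sample_design(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> List[Tuple[str, int]]:
    """Per-participant (first_contestant, evidence1) design cells.

    Contestant order is counterbalanced exactly (n//2 longer-first),
    then shuffled; the evidence value is drawn from the order's
    admissible set with the configured condition weights, which by
    default put extra mass on the weak values so all 4 strength
    conditions |evidence - 5| in {1, 2, 3, 4} appear.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_participants
    orders = np.array(["longer"] * (n // 2) + ["shorter"] * (n - n // 2))
    rng.shuffle(orders)
    cells = []
    for order in orders:
        values = np.array(_EVIDENCE_SETS[order])
        w = np.array([config.condition_weights.get(int(v), 0.0) for v in values])
        if w.sum() <= 0:
            raise ValueError(f"condition weights assign no mass to the {order}-first evidence set")
        evidence = int(rng.choice(values, p=w / w.sum()))
        cells.append((str(order), evidence))
    return cells


def simulate_speaker_phase(
    participant_type: str,
    contestant: str,
    rng: np.random.Generator,
    hedging: str = "interior",
) -> Tuple[int, ...]:
    """Ranking of the example sticks a participant expects the contestant to show.

    A pragmatic participant ranks by descending persuasive utility for
    the contestant's agenda (so 9 first for the long-biased contestant,
    2 first for the short-biased one).  A literal participant hedges:
    their rank-1 stick is drawn per the hedging policy ("interior":
    uniform over {4, 7, 8}; "non-strongest": uniform over the four
    sticks other than the contestant's strongest; "uniform": uniform
    over all five) and the remaining sticks are ordered randomly.
    """
    if participant_type == "pragmatic":
        return tuple(
            sorted(EXAMPLE_STICKS, key=lambda u: persuasive_utility(u, contestant), reverse=True)
        )
    if participant_type != "literal":
        raise ValueError(f"participant type must be 'pragmatic' or 'literal', got {participant_type!r}")
    if hedging == "interior":
        pool = [u for u in EXAMPLE_STICKS if u not in STRONGEST.values()]
    elif hedging == "non-strongest":
        pool = [u for u in EXAMPLE_STICKS if u != STRONGEST[contestant]]
    elif hedging == "uniform":
        pool = list(EXAMPLE_STICKS)
    else:
        raise ValueError(f"hedging must be one of {HEDGING_POLICIES}")
    first = int(rng.choice(pool))
    rest = [u for u in EXAMPLE_STICKS if u != first]
    rng.shuffle(rest)
    return (first, *rest)


def simulate_listener_phase(
    participant_type: str,
    first_contestant: str,
    evidence1: int,
    beta_true: float,
    response: ResponseParams,
    rng: np.random.Generator,
) -> float:
    """Slider response to the first piece of evidence, in [0, 100].

    Pragmatic types respond around the pragmatic listener's belief at
    ``beta_true``; literal types around the literal listener's.  The
    predicted slider gets Gaussian noise (sd = 100 * noise_sd) and is
    clipped to the scale.
    """
    if participant_type == "pragmatic":
        belief = pragmatic_listener(evidence1, first_contestant, SpeakerParams(beta=beta_true))
    elif participant_type == "literal":
        belief = literal_listener(evidence1)
    else:
        raise ValueError(f"participant type must be 'pragmatic' or 'literal', got {participant_type!r}")
    mean = predicted_slider(belief, response)
    slider = mean + rng.normal(0.0, 100.0 * response.noise_sd)
    return float(min(100.0, max(0.0, slider)))


def generate_records(config: GeneratorConfig = GeneratorConfig()) -> List[ParticipantRecord]:
    """Generate a fully validated synthetic participant table.

    Both phases share one contestant order per participant, so a
    participant's speaker-phase choice and listener-phase response are
    linked through their type -- the structure the speaker-dependent
    model is designed to detect.  Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cells = sample_design(config, rng)
    types = np.where(rng.random(config.n_participants) < config.p_pragmatic, "pragmatic", "literal")
    records = []
    for i, ((order, evidence), ptype) in enumerate(zip(cells, types)):
        ranking = simulate_speaker_phase(str(ptype), order, rng, config.hedging)
        slider = simulate_listener_phase(
            str(ptype), order, evidence, config.beta_true, config.response, rng
        )
        records.append(
            ParticipantRecord(
                id=f"p{i + 1:04d}",
                first_contestant=order,
                speaker_rank1=ranking[0],
                evidence1=evidence,
                slider1=slider,
            )
        )
    logger.info(
        "generated %d participants (seed=%d, config=%s)",
        len(records), config.seed, config.digest(),
    )
    return records


def generate_dataset(config: GeneratorConfig = GeneratorConfig()) -> pd.DataFrame:
    """Synthetic participant table as a DataFrame in the canonical CSV schema."""
    return records_to_frame(generate_records(config))
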