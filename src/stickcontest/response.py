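"""Response model: from verdict beliefs to slider responses and likelihoods.

Participants report their verdict belief on a 0-100 slider (0 = average
definitely shorter, 100 = definitely longer).  A model's belief is
mapped to the slider by an additive *offset* on the probability scale
followed by clipping, and responses are assumed Gaussian around the
prediction (on the probability scale) with a free, shared noise sd.

Six model variants are scored:

======================  =====================================================
``aa-hom``              anchor-and-adjust, neutral anchor (eta=0.5, R=0)
``mas-hom``             minimum-acceptable-strength: free anchor and eta
``mas-het``             mixture of the MAS and simple-AA components
``rsa-hom``             every participant a pragmatic listener (J1)
``rsa-het``             one population mixture of pragmatic J1 / literal J0
``rsa-speaker``         J1/J0 mixture weights fit per speaker-phase sub-group
======================  =====================================================

The speaker-dependent variant keys its mixture weights by the stick a
participant said the first contestant would reveal first (out of the
example set {2, 4, 7, 8, 9}), asking whether speaker expectations
predict listener behaviour.  Latent assignments are always marginalised
analytically, never sampled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .baselines import AAParams, aa_update, evidence_strength
from .core import (
    MIDPOINT,
    SpeakerParams,
    VerdictBelief,
    _pragmatic_p_longer_all,
    _tables,
    literal_listener,
    pragmatic_listener,
)

__all__ = [
    "EXAMPLE_STICKS",
    "VARIANTS",
    "ResponseParams",
    "MixtureParams",
    "ParticipantRecord",
    "DataError",
    "predicted_slider",
    "participant_loglik",
    "dataset_loglik",
    "DatasetEvaluator",
    "read_participants",
    "write_participants",
    "records_to_frame",
    "belief_curves",
    "weak_evidence_means",
]

logger = logging.getLogger(__name__)

#: The example stick set shown in the speaker-expectation phase.
EXAMPLE_STICKS = (2, 4, 7, 8, 9)

#: The extreme (most persuasive) stick of the example set per agenda.
STRONGEST = {"longer": 9, "shorter": 2}

#: Canonical participant CSV header.
CSV_COLUMNS = ["id", "first_contestant", "speaker_rank1", "evidence1", "slider1"]

_EVIDENCE_SETS = {"longer": (6, 7, 8, 9), "shorter": (1, 2, 3, 4)}

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class DataError(ValueError):
    """Raised when an input participant table violates the schema."""


@dataclass(frozen=True)
class ResponseParams:
    """Additive slider offset and response noise, both on the probability scale.

    ``noise_sd = 0`` is allowed as the noiseless limit when generating
    synthetic responses; likelihood evaluation requires a positive sd
    (enforced by the inference priors).
    """

    offset: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if not self.noise_sd >= 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (-1.0 <= self.offset <= 1.0):
            raise ValueError("offset must lie in [-1, 1]")


@dataclass(frozen=True)
class MixtureParams:
    """Mixture weights over sub-group labels; each weight is the probability
    that the sub-group's responses come from the pragmatic (J1) component."""

    weights: Mapping[str, float]

    def __post_init__(self):
        for label, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"weight for {label!r} must lie in [0, 1], got {w}")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: condition, speaker-phase choice, first slider response.

    ``group`` is derived: "strongest-expected" when the participant
    expected the first contestant to lead with its most persuasive stick
    (9 for the long-biased contestant, 2 for the short-biased one).
    """

    id: str
    first_contestant: str
    speaker_rank1: int
    evidence1: int
    slider1: float

    def __post_init__(self):
        if self.first_contestant not in ("longer", "shorter"):
            raise ValueError(
                f"first_contestant must be 'longer' or 'shorter', got {self.first_contestant!r}"
            )
        if self.speaker_rank1 not in EXAMPLE_STICKS:
            raise ValueError(
                f"speaker_rank1 must be one of {EXAMPLE_STICKS}, got {self.speaker_rank1!r}"
            )
        if self.evidence1 not in _EVIDENCE_SETS[self.first_contestant]:
            raise ValueError(
                f"evidence1={self.evidence1!r} invalid for a {self.first_contestant}-biased "
                f"first contestant (must be in {_EVIDENCE_SETS[self.first_contestant]})"
            )
        if not (0.0 <= self.slider1 <= 100.0):
            raise ValueError(f"slider1 must lie in [0, 100], got {self.slider1!r}")

    @property
    def group(self) -> str:
        expected_strongest = self.speaker_rank1 == STRONGEST[self.first_contestant]
        return "strongest-expected" if expected_strongest else "other"


def predicted_slider(belief: VerdictBelief, params: ResponseParams) -> float:
    """Map a verdict belief to the expected slider response in [0, 100]."""
    return 100.0 * min(1.0, max(0.0, belief.p_longer + params.offset))


# ---------------------------------------------------------------------------
# Variant registry and likelihoods
# ---------------------------------------------------------------------------

#: Parameter names, in canonical order, for each model variant.
VARIANTS: Dict[str, Tuple[str, ...]] = {
    "aa-hom": ("offset", "noise_sd"),
    "mas-hom": ("anchor", "eta", "offset", "noise_sd"),
    "mas-het": ("w_mas", "anchor", "eta", "offset", "noise_sd"),
    "rsa-hom": ("beta", "offset", "noise_sd"),
    "rsa-het": ("w_prag", "beta", "offset", "noise_sd"),
    "rsa-speaker": ("w_2", "w_4", "w_7", "w_8", "w_9", "beta", "offset", "noise_sd"),
}


def _check_variant(variant: str) -> str:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")
    return variant


def _component_p_longer(component: str, rec: ParticipantRecord, params: Mapping[str, float]) -> float:
    if component == "J0":
        return literal_listener(rec.evidence1).p_longer
    if component == "J1":
        return pragmatic_listener(
            rec.evidence1, rec.first_contestant, SpeakerParams(beta=params["beta"])
        ).p_longer
    if component == "AA":
        return aa_update(0.5, rec.evidence1)
    if component == "MAS":
        return aa_update(0.5, rec.evidence1, AAParams(eta=params["eta"], anchor=params["anchor"]))
    raise ValueError(f"unknown component {component!r}")


def _mixture(variant: str, rec: ParticipantRecord, params: Mapping[str, float]):
    """(weight, component) pairs for one participant under a variant."""
    if variant == "aa-hom":
        return [(1.0, "AA")]
    if variant == "mas-hom":
        return [(1.0, "MAS")]
    if variant == "mas-het":
        w = params["w_mas"]
        return [(w, "MAS"), (1.0 - w, "AA")]
    if variant == "rsa-hom":
        return [(1.0, "J1")]
    if variant == "rsa-het":
        w = params["w_prag"]
        return [(w, "J1"), (1.0 - w, "J0")]
    if variant == "rsa-speaker":
        key = f"w_{rec.speaker_rank1}"
        if key not in params:
            raise ValueError(f"missing mixture weight {key!r} for sub-group {rec.speaker_rank1}")
        w = params[key]
        return [(w, "J1"), (1.0 - w, "J0")]
    raise ValueError(f"unknown variant {variant!r}")


def _normal_logpdf(y: float, mean: float, sd: float) -> float:
    z = (y - mean) / sd
    return -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI


def participant_loglik(
    rec: ParticipantRecord, variant: str, params: Mapping[str, float]
) -> float:
    """Log-likelihood of one participant's slider under a model variant.

    The slider (rescaled to [0, 1]) is Gaussian around the predicted
    probability; mixtures are the log of the convex combination of
    component densities, i.e. the latent assignment is marginalised.
    """
    _check_variant(variant)
    offset, sd = params["offset"], params["noise_sd"]
    y = rec.slider1 / 100.0
    terms = []
    for w, component in _mixture(variant, rec, params):
        if w == 0.0:
            continue
        p = _component_p_longer(component, rec, params)
        mean = min(1.0, max(0.0, p + offset))
        terms.append(math.log(w) + _normal_logpdf(y, mean, sd))
    if not terms:
        raise ValueError("mixture has no components with positive weight")
    m = max(terms)
    return m + math.log(sum(math.exp(t - m) for t in terms))


def dataset_loglik(
    records: Sequence[ParticipantRecord], variant: str, params: Mapping[str, float]
):
    """Total and per-participant log-likelihood, order-stable.

    Returns ``(total, pointwise)`` where ``pointwise`` is a float array
    aligned with ``records``.
    """
    if not len(records):
        raise ValueError("records must be nonempty")
    pointwise = DatasetEvaluator(records, variant).pointwise(params)
    return float(pointwise.sum()), pointwise


class DatasetEvaluator:
    """Vectorised pointwise log-likelihood for repeated evaluation.

    Precomputes per-record arrays once so MCMC and optimisation pay only
    O(n) numpy work per parameter vector.  Agrees with the per-record
    :func:`participant_loglik` path exactly.
    """

    def __init__(self, records: Sequence[ParticipantRecord], variant: str):
        self.variant = _check_variant(variant)
        self.records = list(records)
        if not self.records:
            raise ValueError("records must be nonempty")
        self.n = len(self.records)
        self.y = np.array([r.slider1 / 100.0 for r in self.records])
        self.u = np.array([r.evidence1 for r in self.records])
        self.is_longer = np.array([r.first_contestant == "longer" for r in self.records])
        self.rank = np.array([r.speaker_rank1 for r in self.records])
        self.strength = np.array([evidence_strength(int(u)) for u in self.u])
        l0_longer = _tables()[3]
        self.p_j0 = l0_longer[self.u - 1]
        self.p_aa = np.clip(0.5 + 0.5 * self.strength, 0.0, 1.0)

    def _loglik_terms(self, p: np.ndarray, offset: float, sd: float) -> np.ndarray:
        mean = np.clip(p + offset, 0.0, 1.0)
        z = (self.y - mean) / sd
        return -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI

    def _p_j1(self, beta: float) -> np.ndarray:
        p_long = _pragmatic_p_longer_all("longer", beta)
        # mirror symmetry of the uniform prior about the midpoint:
        # P(longer | u, shorter agenda) = 1 - P(longer | 10-u, longer agenda)
        p_short = 1.0 - p_long[::-1]
        return np.where(self.is_longer, p_long[self.u - 1], p_short[self.u - 1])

    def pointwise(self, params: Mapping[str, float]) -> np.ndarray:
        offset, sd = params["offset"], params["noise_sd"]
        v = self.variant
        if v == "aa-hom":
            return self._loglik_terms(self.p_aa, offset, sd)
        if v == "mas-hom":
            p = np.clip(0.5 + params["eta"] * (self.strength - params["anchor"]), 0.0, 1.0)
            return self._loglik_terms(p, offset, sd)
        if v == "mas-het":
            p_mas = np.clip(0.5 + params["eta"] * (self.strength - params["anchor"]), 0.0, 1.0)
            return self._mix(params["w_mas"], p_mas, self.p_aa, offset, sd)
        if v == "rsa-hom":
            return self._loglik_terms(self._p_j1(params["beta"]), offset, sd)
        if v == "rsa-het":
            return self._mix(params["w_prag"], self._p_j1(params["beta"]), self.p_j0, offset, sd)
        if v == "rsa-speaker":
            try:
                w = np.array([params[f"w_{r}"] for r in self.rank])
            except KeyError as exc:  # pragma: no cover - defensive
                raise ValueError(f"missing mixture weight {exc}") from exc
            return self._mix(w, self._p_j1(params["beta"]), self.p_j0, offset, sd)
        raise ValueError(f"unknown variant {v!r}")

    def _mix(self, w, p1, p0, offset, sd) -> np.ndarray:
        ll1 = self._loglik_terms(p1, offset, sd)
        ll0 = self._loglik_terms(p0, offset, sd)
        with np.errstate(divide="ignore"):
            return np.logaddexp(np.log(w) + ll1, np.log1p(-np.minimum(w, 1.0)) + ll0)

    def total(self, params: Mapping[str, float]) -> float:
        return float(self.pointwise(params).sum())


# ---------------------------------------------------------------------------
# Participant CSV interface
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Canonical participant table (the five schema columns) as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "first_contestant": r.first_contestant,
                "speaker_rank1": r.speaker_rank1,
                "evidence1": r.evidence1,
                "slider1": r.slider1,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )


def write_participants(records: Sequence[ParticipantRecord], path) -> None:
    """Write a participant table with the canonical header."""
    records_to_frame(records).to_csv(path, index=False)


def read_participants(path) -> List[ParticipantRecord]:
    """Read and validate a participant CSV.

    The header must be exactly ``id,first_contestant,speaker_rank1,
    evidence1,slider1``.  Rows violating the record invariants are
    rejected and logged with their line number; a table with a bad
    header or no valid rows raises :class:`DataError`.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != CSV_COLUMNS:
        raise DataError(
            f"bad header in {path}: expected {','.join(CSV_COLUMNS)}, "
            f"got {','.join(frame.columns)}"
        )
    records: List[ParticipantRecord] = []
    n_rejected = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            records.append(
                ParticipantRecord(
                    id=str(row.id),
                    first_contestant=str(row.first_contestant),
                    speaker_rank1=int(row.speaker_rank1),
                    evidence1=int(row.evidence1),
                    slider1=float(row.slider1),
                )
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("rejected line %d of %s: %s", line, path, exc)
    if not records:
        raise DataError(f"no valid participant rows in {path} ({n_rejected} rejected)")
    if n_rejected:
        logger.warning("%d of %d rows rejected in %s", n_rejected, len(frame), path)
    return records


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def belief_curves(beta: float, response: ResponseParams) -> pd.DataFrame:
    """Predicted slider curves of the literal (J0) and pragmatic (J1)
    listeners over all nine evidence values from a long-biased speaker."""
    rows = []
    for u in range(1, 10):
        j0 = predicted_slider(literal_listener(u), response)
        j1 = predicted_slider(pragmatic_listener(u, "longer", SpeakerParams(beta)), response)
        rows.append({"evidence": u, "J0": j0, "J1": j1})
    return pd.DataFrame(rows, columns=["evidence", "J0", "J1"])


def oriented_slider(rec: ParticipantRecord) -> float:
    """Slider re-expressed as endorsement of the first contestant's verdict."""
    return rec.slider1 if rec.first_contestant == "longer" else 100.0 - rec.slider1


def weak_evidence_means(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Mean endorsement of the first contestant's verdict after *weak*
    evidence (|evidence - 5| = 1), split by speaker-expectation group.

    Values below 50 mean the weak evidence backfired on average.
    """
    rows = [
        {"group": r.group, "endorsement": oriented_slider(r)}
        for r in records
        if abs(r.evidence1 - MIDPOINT) == 1
    ]
    frame = pd.DataFrame(rows, columns=["group", "endorsement"])
    return frame.groupby("group")["endorsement"].agg(["mean", "count"])
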