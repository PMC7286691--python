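"""Synthetic permanganate-footprinting data with known ground truth.

The generative model mirrors the assay: each DNA molecule is independently
oxidized at thymine ``i`` with probability ``q_i = 1 - exp(-k_i * a_r * t)``
(first-order kinetics over the quench time ``t``, with a per-replicate-set
permanganate activity multiplier ``a_r``); piperidine cleavage then reveals
only the label-proximal-most oxidized thymine, because the labeled fragment
ends at the cleavage site closest to the label.  Band ``i`` therefore counts
molecules whose first oxidation (in label-proximal order) sits at thymine
``i``, and the last band counts unoxidized, full-length molecules.

Optional stress features emulate the assay's known caveats: a chain reaction
in which an oxidized thymine unstacks its neighbour toward the labeled end
and exposes it to further oxidation; uniform background signal; and off-gel
truncation of the shortest fragments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reactivity import LaneProfile, ValidationError

_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class TrueRateProfile:
    """Ground-truth per-thymine oxidation rate constants for one substrate.

    ``rates`` are ordered label-proximal first (min^-1); ``reference_index``
    points at the reference thymine used for cross-replicate normalization
    (0-based into ``rates``); ``positions`` are the reported thymine
    positions, defaulting to band order.
    """

    substrate_id: str
    rates: tuple[float, ...]
    quench_time_min: float
    reference_index: int | None = None
    positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.rates) < 1:
            raise ValidationError("need at least one thymine")
        if any(r < 0 for r in self.rates):
            raise ValidationError("oxidation rates must be >= 0")
        if self.quench_time_min <= 0:
            raise ValidationError("quench time must be > 0")
        if self.reference_index is not None and not (
            0 <= self.reference_index < len(self.rates)
        ):
            raise ValidationError("reference_index out of range")
        if self.positions is not None and len(self.positions) != len(self.rates):
            raise ValidationError("positions must align with rates")

    @property
    def n_thymines(self) -> int:
        return len(self.rates)

    def band_positions(self) -> tuple[int, ...]:
        return self.positions if self.positions is not None else tuple(
            range(1, self.n_thymines + 1)
        )


@dataclass(frozen=True)
class ReplicateActivity:
    """Multiplicative permanganate-activity factor of one replicate set."""

    replicate_set_id: str
    activity_factor: float

    def __post_init__(self) -> None:
        if self.activity_factor <= 0:
            raise ValidationError("activity factor must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling settings; the seed is mandatory (no hidden global RNG)."""

    n_molecules: int
    seed: int
    chain_reaction_prob: float = 0.0
    truncate_below_band: int | None = None
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        if not 0.0 <= self.chain_reaction_prob <= 1.0:
            raise ValidationError("chain_reaction_prob must be in [0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValidationError("background_fraction must be in [0, 1)")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


def oxidation_probs(profile: TrueRateProfile, activity: ReplicateActivity) -> np.ndarray:
    """Per-thymine oxidation probabilities ``q_i = 1 - exp(-k_i a_r t)``."""
    k = np.asarray(profile.rates, dtype=float)
    return -np.expm1(-k * activity.activity_factor * profile.quench_time_min)


def _band_probabilities(q: np.ndarray) -> np.ndarray:
    """Closed-form band distribution under independent oxidation.

    P(band i) = q_i * prod_{j<i} (1 - q_j); P(full length) = prod (1 - q_j).
    """
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    return np.concatenate([q * surv[:-1], surv[-1:]])


def simulate_lane(
    profile: TrueRateProfile,
    activity: ReplicateActivity,
    config: SimulationConfig,
    lane_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> LaneProfile:
    """Simulate one gel lane of ``config.n_molecules`` molecules.

    Without chain reactions the observed band is multinomial with the
    closed-form distribution above.  With ``chain_reaction_prob = c > 0``,
    each primary oxidation at thymine ``i`` propagates recursively toward the
    labeled end (to ``i-1`` with probability ``c``, then ``i-2`` ...), so the
    chain length is geometric and the recorded band — the label-proximal-most
    oxidized thymine — shifts toward band 1.  Background is added as a
    uniform pseudocount fraction of the total; truncation zeroes the bands
    that ran off the gel and flags the lane.
    """
    m = profile.n_thymines
    q = oxidation_probs(profile, activity)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    if config.chain_reaction_prob == 0.0:
        counts = rng.multinomial(n, _band_probabilities(q)).astype(float)
    else:
        c = config.chain_reaction_prob
        oxidized = rng.random((n, m)) < q  # primary events
        # chain extension toward the label from every primary event
        ext = rng.geometric(1.0 - c, size=(n, m)) - 1
        idx = np.arange(1, m + 1)
        reach = np.where(oxidized, np.maximum(idx - ext, 1), m + 1)
        band = reach.min(axis=1)  # m+1 == full length
        counts = np.bincount(band, minlength=m + 2)[1:].astype(float)
    if config.background_fraction > 0.0:
        total = counts.sum()
        bg = config.background_fraction * total / (1.0 - config.background_fraction)
        counts += bg / (m + 1)
    lane = LaneProfile(
        substrate_id=profile.substrate_id,
        replicate_set_id=activity.replicate_set_id,
        band_volumes=tuple(counts),
        thymine_positions=profile.band_positions(),
        lane_id=lane_id or f"{profile.substrate_id}:{activity.replicate_set_id}",
    )
    if config.truncate_below_band is not None:
        lane = lane.truncate(config.truncate_below_band)
    return lane


def enumerate_expected_lane(
    profile: TrueRateProfile,
    activity: ReplicateActivity,
    lane_id: str | None = None,
) -> LaneProfile:
    """Exact expected band fractions by brute-force enumeration.

    Walks all ``2^m`` oxidation patterns, multiplies Bernoulli probabilities
    and assigns each pattern to its observed band (label-proximal-most
    oxidized thymine, else full length).  Serves as the sampling-free oracle
    for :func:`simulate_lane`; refuses ``m > 20``.
    """
    m = profile.n_thymines
    if m > _ENUMERATION_LIMIT:
        raise ValidationError(
            f"{m} thymines would need 2^{m} patterns; use simulate_lane for m > "
            f"{_ENUMERATION_LIMIT}"
        )
    q = oxidation_probs(profile, activity)
    fractions = np.zeros(m + 1)
    for pattern in itertools.product((False, True), repeat=m):
        prob = 1.0
        for qi, ox in zip(q, pattern):
            prob *= qi if ox else 1.0 - qi
        band = next((i for i, ox in enumerate(pattern) if ox), m)  # m == full length
        fractions[band] += prob
    lane_id = lane_id or f"{profile.substrate_id}:{activity.replicate_set_id}:expected"
    return LaneProfile(
        substrate_id=profile.substrate_id,
        replicate_set_id=activity.replicate_set_id,
        band_volumes=tuple(fractions),
        thymine_positions=profile.band_positions(),
        lane_id=lane_id,
    )


def simulate_experiment(
    profiles: Sequence[TrueRateProfile],
    replicate_sets: Sequence[ReplicateActivity],
    config: SimulationConfig,
) -> list[LaneProfile]:
    """Simulate a full multi-substrate, multi-replicate-set experiment.

    One lane per (substrate, replicate set); lanes within a replicate set
    share its activity factor, which the reference-thymine correction in
    :mod:`rloopflank.reactivity` should remove.  Every profile must designate
    its reference thymine, and all reference thymines must share one true
    rate (the premise of using a common reference across substrates).
    """
    ref_rates = set()
    for prof in profiles:
        if prof.reference_index is None:
            raise ValidationError(
                f"substrate {prof.substrate_id!r} lacks a reference thymine"
            )
        ref_rates.add(prof.rates[prof.reference_index])
    if len(ref_rates) > 1:
        raise ValidationError(
            f"reference thymines must share one true rate, got {sorted(ref_rates)}"
        )
    rng = np.random.default_rng(config.seed)
    lanes = []
    for activity in replicate_sets:
        for prof in profiles:
            lanes.append(
                simulate_lane(
                    prof,
                    activity,
                    config,
                    lane_id=f"{prof.substrate_id}:{activity.replicate_set_id}",
                    rng=rng,
                )
            )
    return lanes


def lognormal_activities(
    replicate_set_ids: Sequence[str],
    sigma: float,
    rng: np.random.Generator,
) -> list[ReplicateActivity]:
    """Draw multiplicative activity factors, lognormal(mu=0, sigma)."""
    return [
        ReplicateActivity(replicate_set_id=s, activity_factor=float(a))
        for s, a in zip(replicate_set_ids, rng.lognormal(0.0, sigma, len(replicate_set_ids)))
    ]
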