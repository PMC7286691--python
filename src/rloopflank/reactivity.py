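"""Permanganate footprinting statistics for R-loop flank conformation.

Permanganate oxidizes thymines whose C5=C6 bond is solvent-approachable
(distorted, melted or flipped-out DNA); piperidine then cleaves the backbone
at oxidized thymines, and the radiolabeled cleavage fragments are resolved on
a denaturing gel.  Each gel lane yields ordered band volumes ``v_1..v_n``
(band 1 = shortest fragment = cleavage at the thymine closest to the labeled
end; band n = full-length, uncleaved DNA).

This module turns those volumes into:

* per-thymine oxidation probabilities ``p_i`` (a conditional frequency that
  is immune to signal "stolen" by more label-proximal cleavages),
* first-order oxidation rate constants ``k_i``,
* cross-replicate corrected rates ``k_i_corr`` via a reference thymine whose
  conformation is unaffected by R-loop formation,
* the Permanganate Reactivity Index ``PRI_i = k_i_corr / kss_corr``
  (normalized so a fully single-stranded thymine scores 1), and
* the Fraction Oxidized ``FO`` of a substrate's R-loop flank (the estimated
  fraction of molecules oxidized on at least one flank thymine at quench).

All estimators assume independent oxidation events across thymines; the
companion :mod:`rloopflank.synthetic` module can stress that assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default reference-corrected rate constant (min^-1) of a thymine with no
#: stable base-pairing partner; PRI = 1 at this rate.
DEFAULT_KSS_CORR = 0.79

#: Oxidation probabilities at or above this value are flagged saturated: the
#: log transform k = ln(1/(1-p))/t amplifies noise without bound as p -> 1.
DEFAULT_SATURATION_THRESHOLD = 0.99

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


class ValidationError(ValueError):
    """Raised when an input object violates its documented invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LaneProfile:
    """One gel lane: ordered band volumes, label-proximal first.

    ``band_volumes[i]`` is the integrated signal of band ``i+1``; the final
    entry is always the full-length (uncleaved) band.  ``thymine_positions``
    gives the probed position (1-based along the labeled strand, counted from
    the labeled end) for each cleavage band; the full-length band carries none.
    ``first_present_band`` marks off-gel truncation: bands with index below it
    ran off the bottom of the gel and their volumes are meaningless.
    """

    substrate_id: str
    replicate_set_id: str
    band_volumes: tuple[float, ...]
    thymine_positions: tuple[int, ...]
    label_end: str = FIVE_PRIME
    labeled_strand: str | None = None
    lane_id: str | None = None
    first_present_band: int = 1

    def __post_init__(self) -> None:
        n = len(self.band_volumes)
        if n < 2:
            raise ValidationError(
                f"lane {self.lane_id!r}: need >= 2 bands (cleavage + full length), got {n}"
            )
        if len(self.thymine_positions) != n - 1:
            raise ValidationError(
                f"lane {self.lane_id!r}: {n} bands require {n - 1} thymine positions, "
                f"got {len(self.thymine_positions)}"
            )
        if any(v < 0 for v in self.band_volumes):
            raise ValidationError(f"lane {self.lane_id!r}: negative band volume")
        if not math.isfinite(sum(self.band_volumes)):
            raise ValidationError(f"lane {self.lane_id!r}: non-finite band volume")
        if self.label_end not in (FIVE_PRIME, THREE_PRIME):
            raise ValidationError(f"lane {self.lane_id!r}: bad label_end {self.label_end!r}")
        if not 1 <= self.first_present_band <= n:
            raise ValidationError(
                f"lane {self.lane_id!r}: first_present_band {self.first_present_band} "
                f"outside 1..{n}"
            )

    @property
    def n_bands(self) -> int:
        return len(self.band_volumes)

    def truncate(self, first_present_band: int) -> "LaneProfile":
        """Return a copy with bands below ``first_present_band`` zeroed and flagged."""
        vols = tuple(
            0.0 if i + 1 < first_present_band else v for i, v in enumerate(self.band_volumes)
        )
        return replace(self, band_volumes=vols, first_present_band=first_present_band)

    def scale(self, c: float) -> "LaneProfile":
        if c <= 0:
            raise ValidationError("scale factor must be positive")
        return replace(self, band_volumes=tuple(c * v for v in self.band_volumes))


@dataclass(frozen=True)
class RlfMember:
    """One R-loop-flank thymine: its display label, strand and position."""

    label: str
    strand: str
    position: int


@dataclass(frozen=True)
class SubstrateMap:
    """Substrate annotation needed to interpret lanes of one labeling.

    Positions are 1-based along the labeled strand, counted from the labeled
    end.  ``rlf_members`` may reference thymines on either strand; members on
    the non-labeled strand are resolved from the reactivity profile of the
    complementary labeling when FO is computed.
    """

    substrate_id: str
    strand_sequences: Mapping[str, str]
    labeled_strand: str
    probed_thymines: tuple[int, ...]
    reference_thymine: int
    quench_time_min: float
    label_end: str = FIVE_PRIME
    rlf_members: tuple[RlfMember, ...] = ()

    def __post_init__(self) -> None:
        if self.labeled_strand not in self.strand_sequences:
            raise ValidationError(
                f"substrate {self.substrate_id!r}: labeled strand "
                f"{self.labeled_strand!r} not among strands {list(self.strand_sequences)}"
            )
        if self.quench_time_min <= 0:
            raise ValidationError(f"substrate {self.substrate_id!r}: quench time must be > 0")
        if self.reference_thymine not in self.probed_thymines:
            raise ValidationError(
                f"substrate {self.substrate_id!r}: reference thymine "
                f"{self.reference_thymine} is not a probed position"
            )
        seq = self.strand_sequences[self.labeled_strand].upper()
        for pos in self.probed_thymines:
            if not 1 <= pos <= len(seq):
                raise ValidationError(
                    f"substrate {self.substrate_id!r}: position {pos} outside strand "
                    f"{self.labeled_strand!r} (length {len(seq)})"
                )
            base = self._base_at(seq, pos)
            if base != "T":
                raise ValidationError(
                    f"substrate {self.substrate_id!r}: probed position {pos} on strand "
                    f"{self.labeled_strand!r} is {base!r}, not a thymine"
                )

    def _base_at(self, seq: str, pos: int) -> str:
        # positions count from the labeled end: from the left for a 5' label,
        # from the right for a 3' label
        return seq[pos - 1] if self.label_end == FIVE_PRIME else seq[len(seq) - pos]


@dataclass(frozen=True)
class OxidationProfile:
    """Per-thymine oxidation probabilities ``p_i`` for one lane.

    ``p[j]`` is NaN where undefined (truncated band or zero denominator);
    ``missing[j]`` is True there.
    """

    substrate_id: str
    replicate_set_id: str
    thymine_positions: tuple[int, ...]
    p: tuple[float, ...]
    missing: tuple[bool, ...]
    labeled_strand: str | None = None
    lane_id: str | None = None


@dataclass(frozen=True)
class CorrectionModel:
    """Reference-thymine normalization of permanganate activity.

    Each replicate set used a fresh permanganate preparation whose oxidation
    activity varies; the mean reference-thymine rate of a set, ``kbar_ref``,
    captures that activity, and the grand mean ``mu_ref`` across sets is taken
    as the reference thymine's true rate.  Rates in set ``r`` are multiplied
    by ``mu_ref / kbar_ref[r]``.
    """

    kbar_ref: Mapping[str, float]
    mu_ref: float
    kss_corr: float = DEFAULT_KSS_CORR

    def __post_init__(self) -> None:
        if self.kss_corr <= 0:
            raise ValidationError("kss_corr must be > 0")
        if self.mu_ref <= 0 or any(v <= 0 for v in self.kbar_ref.values()):
            raise ValidationError("reference rate constants must be > 0")

    def factor(self, replicate_set_id: str) -> float:
        try:
            return self.mu_ref / self.kbar_ref[replicate_set_id]
        except KeyError:
            raise ValidationError(
                f"replicate set {replicate_set_id!r} not in correction model "
                f"(known: {sorted(self.kbar_ref)})"
            ) from None


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-thymine rates and indices for one lane after correction.

    Arrays are aligned with ``thymine_positions``; NaN plus the matching flag
    marks unavailable values (truncated band, zero denominator, or p = 1).
    """

    substrate_id: str
    replicate_set_id: str
    thymine_positions: tuple[int, ...]
    p: tuple[float, ...]
    k: tuple[float, ...]
    k_corr: tuple[float, ...]
    pri: tuple[float, ...]
    p_corr: tuple[float, ...]
    saturated: tuple[bool, ...]
    missing: tuple[bool, ...]
    truncated: tuple[bool, ...]
    labeled_strand: str | None = None
    lane_id: str | None = None

    def p_corr_at(self, position: int) -> float:
        i = self.thymine_positions.index(position)
        return self.p_corr[i]


@dataclass(frozen=True)
class FOResult:
    """Fraction of molecules oxidized on >= 1 R-loop-flank thymine."""

    substrate_id: str
    fo: float
    members: tuple[RlfMember, ...]
    per_replicate: Mapping[str, float] = field(default_factory=dict)
    mean: float | None = None
    sd: float | None = None


@dataclass(frozen=True)
class Aggregate:
    """Mean and sample standard deviation over replicates."""

    mean: float | np.ndarray
    sd: float | np.ndarray | None
    n: int

    @property
    def sd_available(self) -> bool:
        return self.sd is not None


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def oxidation_probabilities(
    lane: LaneProfile,
    exclude_positions: frozenset[int] | set[int] = frozenset(),
) -> OxidationProfile:
    """Estimate per-thymine oxidation probabilities from one lane.

    For each present cleavage band ``i``,
    ``p_i = v_i / sum_{j >= i, j present} v_j``: out of all molecules for
    which cleavage at thymine ``i`` would have been observable (fragments at
    or above band ``i``), the fraction actually cleaved there.  Because the
    denominator only looks label-distal, ``p_i`` is unaffected by shorter
    fragments — including ones that ran off the gel.

    Faint cleavage bands at cytosines or purines may be annotated via
    ``exclude_positions``: their volumes are then removed from every
    denominator and no probability is reported for them.  By default all
    listed bands count toward denominators, since the denominator is "all
    fragments at or above" regardless of the cleavage chemistry.
    """
    v = np.asarray(lane.band_volumes, dtype=float)
    excluded = np.array(
        [pos in exclude_positions for pos in lane.thymine_positions] + [False]
    )
    v = np.where(excluded, 0.0, v)
    if v.sum() == 0:
        raise ValidationError(f"lane {lane.lane_id!r}: all band volumes are zero")
    n = lane.n_bands
    # cumulative volume at-or-above each band (full-length included)
    tail = np.cumsum(v[::-1])[::-1]
    p = np.full(n - 1, np.nan)
    missing = np.zeros(n - 1, dtype=bool)
    for i in range(n - 1):
        if excluded[i]:
            missing[i] = True
            continue
        if i + 1 < lane.first_present_band:
            missing[i] = True
            continue
        if tail[i] <= 0:
            missing[i] = True
            logger.warning(
                "lane %s: zero denominator at band %d (position %d); p undefined",
                lane.lane_id, i + 1, lane.thymine_positions[i],
            )
            continue
        p[i] = v[i] / tail[i]
    return OxidationProfile(
        substrate_id=lane.substrate_id,
        replicate_set_id=lane.replicate_set_id,
        thymine_positions=lane.thymine_positions,
        p=tuple(p),
        missing=tuple(bool(m) for m in missing),
        labeled_strand=lane.labeled_strand,
        lane_id=lane.lane_id,
    )


def rate_constants(
    profile: OxidationProfile,
    t: float,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert oxidation probabilities to first-order rate constants.

    Oxidation is modeled as a Poisson process over the permanganate exposure
    (uniform hazard up to the quench time ``t``), so ``k_i = ln(1/(1-p_i))/t``.
    Returns ``(k, saturated, missing)``; ``p_i = 1`` has an infinite rate and
    is reported missing, ``p_i >= saturation_threshold`` is flagged saturated
    but still quantified.
    """
    if t <= 0:
        raise ValidationError("quench time must be > 0")
    p = np.asarray(profile.p, dtype=float)
    missing = np.asarray(profile.missing, dtype=bool).copy()
    saturated = np.zeros_like(missing)
    k = np.full_like(p, np.nan)
    for i, pi in enumerate(p):
        if missing[i] or not math.isfinite(pi):
            missing[i] = True
            continue
        if pi >= 1.0:
            missing[i] = True
            saturated[i] = True
            logger.warning(
                "lane %s: p = 1 at position %d; rate is unbounded and reported missing",
                profile.lane_id, profile.thymine_positions[i],
            )
            continue
        if pi >= saturation_threshold:
            saturated[i] = True
        k[i] = math.log1p(-pi) / -t  # ln(1/(1-p))/t, accurate for small p
    return k, saturated, missing


def build_correction(
    reference_rates: Mapping[str, Sequence[float]],
    kss_corr: float = DEFAULT_KSS_CORR,
) -> CorrectionModel:
    """Build the cross-replicate correction from reference-thymine rates.

    ``reference_rates`` maps each replicate-set id to the reference thymine's
    uncorrected rate constants measured in that set's lanes (one per lane /
    substrate).  Per-set means and the grand mean are unweighted.
    """
    kbar: dict[str, float] = {}
    for set_id, values in reference_rates.items():
        vals = [v for v in values if v is not None and math.isfinite(v)]
        if not vals:
            raise ValidationError(
                f"replicate set {set_id!r} has no usable reference-thymine measurement"
            )
        kbar[set_id] = float(np.mean(vals))
    if not kbar:
        raise ValidationError("no replicate sets supplied")
    mu_ref = float(np.mean(list(kbar.values())))
    return CorrectionModel(kbar_ref=kbar, mu_ref=mu_ref, kss_corr=kss_corr)


def correct_and_index(
    profile: OxidationProfile,
    model: CorrectionModel,
    t: float,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> ReactivityProfile:
    """Apply the reference correction and compute PRI and corrected p.

    ``k_corr = (mu_ref / kbar_ref) * k``; ``PRI = k_corr / kss_corr`` (linear
    in the corrected rate, = 1 for a fully single-stranded thymine);
    ``p_corr = 1 - exp(-k_corr * t)`` is the oxidation probability expected
    had the permanganate preparation had its average activity.
    """
    k, saturated, missing = rate_constants(profile, t, saturation_threshold)
    factor = model.factor(profile.replicate_set_id)
    k_corr = factor * k
    pri = k_corr / model.kss_corr
    p_corr = 1.0 - np.exp(-k_corr * t)
    truncated = np.asarray(profile.missing, dtype=bool)
    return ReactivityProfile(
        substrate_id=profile.substrate_id,
        replicate_set_id=profile.replicate_set_id,
        thymine_positions=profile.thymine_positions,
        p=tuple(profile.p),
        k=tuple(k),
        k_corr=tuple(k_corr),
        pri=tuple(pri),
        p_corr=tuple(p_corr),
        saturated=tuple(bool(s) for s in saturated),
        missing=tuple(bool(m) for m in missing),
        truncated=tuple(bool(m) for m in truncated),
        labeled_strand=profile.labeled_strand,
        lane_id=profile.lane_id,
    )


def fraction_oxidized(
    profiles: Iterable[ReactivityProfile],
    substrate: SubstrateMap,
) -> FOResult:
    """Estimate the fraction of molecules oxidized within the R-loop flank.

    Combines corrected per-thymine probabilities across both strand labelings
    (oxidation on the two strands of one molecule is assumed independent):

    ``FO = 1 - prod_{a in RLF} (1 - p_a_corr)
         = 1 - exp(-sum_{a in RLF} k_a_corr * t)``

    Each RLF member must resolve to exactly one corrected probability among
    the supplied profiles (matched on strand and position).
    """
    members = substrate.rlf_members
    if not members:
        raise ValidationError(f"substrate {substrate.substrate_id!r}: empty R-loop-flank set")
    profiles = list(profiles)
    log_surv = 0.0
    absent: list[RlfMember] = []
    for m in members:
        hits = []
        for prof in profiles:
            if prof.substrate_id != substrate.substrate_id:
                continue
            if prof.labeled_strand is not None and prof.labeled_strand != m.strand:
                continue
            if m.position in prof.thymine_positions:
                i = prof.thymine_positions.index(m.position)
                hits.append((prof, i))
        if not hits:
            absent.append(m)
            continue
        if len(hits) > 1:
            raise ValidationError(
                f"R-loop-flank thymine {m.label} (strand {m.strand}, position "
                f"{m.position}) matches {len(hits)} profiles; expected exactly one"
            )
        prof, i = hits[0]
        if prof.missing[i] or not math.isfinite(prof.p_corr[i]):
            absent.append(m)
            continue
        log_surv += math.log1p(-prof.p_corr[i])
    if absent:
        raise ValidationError(
            f"substrate {substrate.substrate_id!r}: no corrected probability for "
            "R-loop-flank thymines "
            + ", ".join(f"{m.label}({m.strand}:{m.position})" for m in absent)
        )
    fo = 1.0 - math.exp(log_surv)
    return FOResult(substrate_id=substrate.substrate_id, fo=fo, members=members)


def fo_from_rates(k_corr_sum: float, t: float) -> float:
    """Exponential-sum form of FO: ``1 - exp(-sum k_a_corr * t)``."""
    return -math.expm1(-k_corr_sum * t)


def quantify_experiment(
    lanes: Sequence[LaneProfile],
    substrates: Sequence[SubstrateMap],
    kss_corr: float = DEFAULT_KSS_CORR,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    reference_override: int | None = None,
) -> tuple[list[ReactivityProfile], CorrectionModel]:
    """Run the full normalization pipeline on a multi-lane experiment.

    Computes per-lane oxidation probabilities, collects the reference
    thymine's uncorrected rate from every lane grouped by replicate set,
    builds the cross-replicate correction and returns corrected profiles
    plus the model.  ``reference_override`` replaces every substrate's
    declared reference position.
    """
    by_substrate = {s.substrate_id: s for s in substrates}
    ox_profiles: list[tuple[OxidationProfile, SubstrateMap]] = []
    reference_rates: dict[str, list[float]] = {}
    for lane in lanes:
        try:
            sub = by_substrate[lane.substrate_id]
        except KeyError:
            raise ValidationError(
                f"lane {lane.lane_id!r}: unknown substrate {lane.substrate_id!r}"
            ) from None
        prof = oxidation_probabilities(lane)
        if prof.labeled_strand is None:
            prof = replace(prof, labeled_strand=sub.labeled_strand)
        ox_profiles.append((prof, sub))
        ref_pos = reference_override or sub.reference_thymine
        if ref_pos not in prof.thymine_positions:
            raise ValidationError(
                f"lane {lane.lane_id!r}: reference thymine {ref_pos} not among "
                f"probed positions {prof.thymine_positions}"
            )
        i = prof.thymine_positions.index(ref_pos)
        k, _, missing = rate_constants(prof, sub.quench_time_min, saturation_threshold)
        if not missing[i]:
            reference_rates.setdefault(lane.replicate_set_id, []).append(float(k[i]))
        else:
            reference_rates.setdefault(lane.replicate_set_id, [])
    model = build_correction(reference_rates, kss_corr)
    corrected = [
        correct_and_index(prof, model, sub.quench_time_min, saturation_threshold)
        for prof, sub in ox_profiles
    ]
    return corrected, model


def aggregate_replicates(values: Sequence) -> Aggregate:
    """Mean and sample SD (n-1 denominator) across replicates.

    Accepts scalars or aligned vectors; with a single replicate the SD is
    flagged unavailable rather than reported as zero.  NaNs propagate.
    """
    vals = [np.asarray(v, dtype=float) for v in values]
    if not vals:
        raise ValidationError("no replicate values supplied")
    arr = np.stack(vals)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(vals) >= 2 else None
    if arr.ndim == 1:
        mean = float(mean)
        sd = None if sd is None else float(sd)
    return Aggregate(mean=mean, sd=sd, n=len(vals))
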