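"""Readers and writers for the pipeline's plain-text formats.

* **Lane tables** (TSV): one row per gel band with columns ``substrate_id``,
  ``replicate_set_id``, ``lane_id``, ``band_index``, ``thymine_position``
  (empty for the full-length band) and ``volume``.  An optional
  ``labeled_strand`` column disambiguates substrates probed in both
  labelings.
* **Substrate definitions** (YAML): strand sequences, labeled strand and
  label end, probed thymine positions, reference thymine, R-loop-flank
  membership and quench time.
* **Result tables** (TSV) with a ``#``-prefixed metadata header.
* **Run configuration** (YAML).

Readers validate strictly and reject malformed input with row/field
coordinates; they never repair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .reactivity import (
    DEFAULT_KSS_CORR,
    DEFAULT_SATURATION_THRESHOLD,
    FIVE_PRIME,
    FOResult,
    LaneProfile,
    ReactivityProfile,
    RlfMember,
    SubstrateMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

LANE_COLUMNS = (
    "substrate_id",
    "replicate_set_id",
    "lane_id",
    "band_index",
    "thymine_position",
    "volume",
)

RESULT_COLUMNS = (
    "substrate_id",
    "replicate_set_id",
    "lane_id",
    "labeled_strand",
    "thymine_position",
    "p",
    "k",
    "k_corr",
    "pri",
    "p_corr",
    "flags",
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide settings, overridable from a YAML config file."""

    kss_corr: float = DEFAULT_KSS_CORR
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD
    time_unit: str = "min"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.kss_corr <= 0:
            raise ValidationError("kss_corr must be > 0")
        if self.time_unit not in ("min", "s"):
            raise ValidationError(f"time_unit must be 'min' or 's', got {self.time_unit!r}")


def to_minutes(value: float, unit: str) -> float:
    """Normalize a quench time to minutes (e.g. a 10 s pulse -> 1/6 min)."""
    if unit in ("min", "minute", "minutes"):
        return float(value)
    if unit in ("s", "sec", "second", "seconds"):
        return float(value) / 60.0
    raise ValidationError(f"unknown time unit {unit!r}")


# ---------------------------------------------------------------------------
# lane tables
# ---------------------------------------------------------------------------


def read_lane_table(path: str | Path) -> list[LaneProfile]:
    """Read a TSV lane table into :class:`LaneProfile` objects.

    Bands are ordered by ``band_index`` (label-proximal first; the writer and
    reader share this convention, so 3'-labeled lanes must already be listed
    in label-proximal order).  Truncation is inferred when the smallest
    ``band_index`` of a lane exceeds 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"thymine_position": "string"})
    missing_cols = [c for c in LANE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing_cols)}")
    lanes: list[LaneProfile] = []
    for lane_id, group in df.groupby("lane_id", sort=True):
        group = group.sort_values("band_index")
        rows = group.index.to_numpy() + 2  # 1-based file rows incl. header
        if group["band_index"].duplicated().any():
            dup = int(group.loc[group["band_index"].duplicated(), "band_index"].iloc[0])
            raise ValidationError(f"{path}: duplicate band_index {dup} in lane {lane_id!r}")
        vols = group["volume"].to_numpy(dtype=float)
        for row, v in zip(rows, vols):
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{path} row {row}: invalid volume {v!r}")
        pos_raw = group["thymine_position"]
        is_full = pos_raw.isna() | (pos_raw.str.strip() == "")
        if int(is_full.sum()) != 1 or not bool(is_full.iloc[-1]):
            raise ValidationError(
                f"{path}: lane {lane_id!r} must have exactly one full-length band "
                "(empty thymine_position) with the maximal band_index"
            )
        positions = tuple(int(p) for p in pos_raw[~is_full])
        sub = group["substrate_id"].iloc[0]
        rep = group["replicate_set_id"].iloc[0]
        strand = None
        if "labeled_strand" in group.columns:
            s = group["labeled_strand"].iloc[0]
            strand = None if pd.isna(s) else str(s)
        first_present = int(group["band_index"].min())
        band_idx = group["band_index"].to_numpy(dtype=int)
        n_total = int(band_idx.max())
        # reinstate zero placeholders for truncated (absent) leading bands
        full_vols = [0.0] * n_total
        for bi, v in zip(band_idx, vols):
            full_vols[bi - 1] = float(v)
        # positions align with present cleavage bands
        full_pos = [0] * (n_total - 1)
        pos_iter = iter(positions)
        for bi, fl in zip(band_idx, is_full):
            if not fl:
                full_pos[bi - 1] = next(pos_iter)
        if first_present > 1:
            logger.info(
                "%s: lane %s starts at band %d; bands 1..%d treated as run off the gel",
                path, lane_id, first_present, first_present - 1,
            )
            for i in range(first_present - 1):
                full_pos[i] = -(i + 1)  # placeholder positions for absent bands
        lanes.append(
            LaneProfile(
                substrate_id=str(sub),
                replicate_set_id=str(rep),
                band_volumes=tuple(full_vols),
                thymine_positions=tuple(full_pos),
                labeled_strand=strand,
                lane_id=str(lane_id),
                first_present_band=first_present,
            )
        )
    if not lanes:
        raise ValidationError(f"{path}: no lanes found")
    return lanes


def write_lane_table(lanes: Iterable[LaneProfile], path: str | Path) -> None:
    """Write lanes to the TSV lane-table format (round-trips with the reader)."""
    rows = []
    any_strand = False
    for lane in lanes:
        for i, v in enumerate(lane.band_volumes):
            if i + 1 < lane.first_present_band:
                continue  # absent: ran off the gel
            full = i == lane.n_bands - 1
            rows.append(
                {
                    "substrate_id": lane.substrate_id,
                    "replicate_set_id": lane.replicate_set_id,
                    "lane_id": lane.lane_id,
                    "band_index": i + 1,
                    "thymine_position": "" if full else lane.thymine_positions[i],
                    "volume": repr(float(v)),
                    "labeled_strand": lane.labeled_strand or "",
                }
            )
            any_strand = any_strand or lane.labeled_strand is not None
    cols = list(LANE_COLUMNS) + (["labeled_strand"] if any_strand else [])
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# substrate definitions
# ---------------------------------------------------------------------------


def read_substrates(path: str | Path) -> list[SubstrateMap]:
    """Read substrate definitions from YAML.

    Each entry gives strand sequences, the labeled strand and end, quench
    time (``quench_time: {value: 2, unit: min}`` or a bare number of
    minutes), probed thymine positions, the reference thymine (defaulted to
    position 10 from the 5'-labeled end when omitted) and optional R-loop-
    flank membership with explicit per-thymine strand assignment.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "substrates" not in doc:
        raise ValidationError(f"{path}: expected a top-level 'substrates' list")
    maps: list[SubstrateMap] = []
    for i, entry in enumerate(doc["substrates"]):
        where = f"{path}: substrates[{i}]"
        try:
            sid = str(entry["substrate_id"])
            strands = {str(k): str(v).upper() for k, v in entry["strands"].items()}
            labeled = str(entry["labeled_strand"])
            label_end = str(entry.get("label_end", FIVE_PRIME))
            probed = tuple(int(p) for p in entry["probed_thymines"])
        except KeyError as exc:
            raise ValidationError(f"{where}: missing field {exc.args[0]!r}") from None
        qt = entry.get("quench_time", None)
        if qt is None:
            raise ValidationError(f"{where}: missing field 'quench_time'")
        if isinstance(qt, dict):
            t_min = to_minutes(float(qt["value"]), str(qt.get("unit", "min")))
        else:
            t_min = float(qt)
        ref = entry.get("reference_thymine")
        if ref is None:
            ref = 10
            logger.info(
                "%s: no reference thymine given; defaulting to position 10 from the "
                "5'-labeled end", where,
            )
        rlf = tuple(
            RlfMember(label=str(m["label"]), strand=str(m["strand"]), position=int(m["position"]))
            for m in entry.get("rlf", [])
        )
        try:
            maps.append(
                SubstrateMap(
                    substrate_id=sid,
                    strand_sequences=strands,
                    labeled_strand=labeled,
                    probed_thymines=probed,
                    reference_thymine=int(ref),
                    quench_time_min=t_min,
                    label_end=label_end,
                    rlf_members=rlf,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
    return maps


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def _flag_tokens(profile: ReactivityProfile, i: int) -> str:
    tokens = []
    if profile.saturated[i]:
        tokens.append("saturated")
    if profile.missing[i]:
        tokens.append("missing")
    if profile.truncated[i]:
        tokens.append("truncated")
    return "|".join(tokens) if tokens else "ok"


def write_results(
    profiles: Sequence[ReactivityProfile],
    fo_results: Sequence[FOResult],
    path: str | Path,
    *,
    kss_corr: float = DEFAULT_KSS_CORR,
    mu_ref: float | None = None,
) -> None:
    """Write per-thymine reactivity and per-substrate FO tables.

    Output is deterministic: fixed column order, ``repr``-rendered floats
    (17 significant digits, lossless round-trip) and a ``#`` metadata header
    recording ``kss_corr``, ``mu_ref`` and the software version.
    """
    path = Path(path)

    def fmt(x: float) -> str:
        return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else repr(float(x))

    lines = [
        f"# rloopflank {__version__}",
        f"# kss_corr\t{fmt(kss_corr)}",
        f"# mu_ref\t{fmt(mu_ref) if mu_ref is not None else 'NA'}",
        "\t".join(RESULT_COLUMNS),
    ]
    for prof in profiles:
        for i, pos in enumerate(prof.thymine_positions):
            lines.append(
                "\t".join(
                    [
                        prof.substrate_id,
                        prof.replicate_set_id,
                        prof.lane_id or "",
                        prof.labeled_strand or "",
                        str(pos),
                        fmt(prof.p[i]),
                        fmt(prof.k[i]),
                        fmt(prof.k_corr[i]),
                        fmt(prof.pri[i]),
                        fmt(prof.p_corr[i]),
                        _flag_tokens(prof, i),
                    ]
                )
            )
    for fo in fo_results:
        mean = fo.mean if fo.mean is not None else fo.fo
        sd = fmt(fo.sd) if fo.sd is not None else "NA"
        lines.append(
            "\t".join(
                [
                    "#FO",
                    fo.substrate_id,
                    fmt(fo.fo),
                    fmt(mean),
                    sd,
                    ",".join(m.label for m in fo.members),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a per-thymine results table (metadata lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def read_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {"kss_corr", "saturation_threshold", "time_unit", "seed", "log_level"}
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**doc)
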