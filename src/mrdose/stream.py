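"""Linac state stream model.

The MR-linac reports its state (jaws, MLC, gantry, cumulative MU, beam
state) as a stream of messages at 5 Hz; each message is interpreted as a
control point.  Between two consecutive control points with the beam on
a :class:`BeamSegment` is created, carrying the MU delivered in that
interval and the aperture held at the start control point
(step-and-shoot assumption; intra-segment jaw/MLC/gantry interpolation
is deliberately not modelled).

Streams are serialized as JSON Lines, one message per line, with keys
``t``, ``gantry_deg``, ``jaws_cm``, ``mlc_cm``, ``mu``, ``beam_on``.
Motion traces use keys ``t``, ``dx_mm``, ``dy_mm``, ``dz_mm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

MAX_DOSE_RATE_MU_PER_MIN = 420.0  # machine maximum for the modelled linac


class InvalidStreamError(ValueError):
    """A linac state stream violates its invariants."""


# ---------------------------------------------------------------------------
# apertures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Aperture:
    """Beam aperture: jaw rectangle plus MLC leaf-pair openings.

    Coordinates are cm in the isocenter plane.  ``u`` is the leaf travel
    direction, ``v`` the leaf-stacking direction (CC).  ``jaws_cm`` is
    ``(u1, u2, v1, v2)``.  ``mlc_cm`` holds two banks of leaf edge
    positions: bank A (lower edge) and bank B (upper edge), one entry per
    leaf pair; pair ``i`` covers the v-strip
    ``[(i - N/2) * w, (i + 1 - N/2) * w]`` with ``w = leaf_width_cm``.
    """

    jaws_cm: tuple[float, float, float, float]
    mlc_cm: tuple[tuple[float, ...], tuple[float, ...]]
    leaf_width_cm: float = 1.0

    def __post_init__(self) -> None:
        u1, u2, v1, v2 = self.jaws_cm
        if u2 < u1 or v2 < v1:
            raise ValueError(f"jaw edges must be ordered, got {self.jaws_cm}")
        a, b = self.mlc_cm
        if len(a) != len(b):
            raise ValueError("MLC banks must have equal leaf counts")
        for i, (ai, bi) in enumerate(zip(a, b)):
            if ai > bi + 1e-12:
                raise ValueError(f"leaf pair {i} crosses: A={ai} > B={bi}")
        if self.leaf_width_cm <= 0:
            raise ValueError("leaf width must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.mlc_cm[0])

    def leaf_strips_cm(self) -> np.ndarray:
        """(N, 2) array of [v_lo, v_hi] per leaf pair (cm)."""
        n = self.n_pairs
        w = self.leaf_width_cm
        lo = (np.arange(n) - n / 2.0) * w
        return np.stack([lo, lo + w], axis=1)

    def to_dict(self) -> dict:
        return {
            "jaws_cm": list(self.jaws_cm),
            "mlc_cm": [list(self.mlc_cm[0]), list(self.mlc_cm[1])],
            "leaf_width_cm": self.leaf_width_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Aperture":
        return cls(
            tuple(d["jaws_cm"]),
            (tuple(d["mlc_cm"][0]), tuple(d["mlc_cm"][1])),
            d.get("leaf_width_cm", 1.0),
        )

    @classmethod
    def open_field(cls, width_cm: float, height_cm: float, n_pairs: int = 16,
                   leaf_width_cm: float = 1.0) -> "Aperture":
        """A rectangular open field, all leaves retracted to the jaw edge."""
        a = tuple([-width_cm / 2.0] * n_pairs)
        b = tuple([width_cm / 2.0] * n_pairs)
        return cls(
            (-width_cm / 2.0, width_cm / 2.0, -height_cm / 2.0, height_cm / 2.0),
            (a, b),
            leaf_width_cm,
        )


# ---------------------------------------------------------------------------
# messages, motion, segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinacStateMessage:
    t: float                 # s
    gantry_deg: float
    aperture: Aperture       # jaw + MLC positions, cm at isocenter
    mu: float                # cumulative monitor units
    beam_on: bool


@dataclass(frozen=True)
class MotionSample:
    t: float
    translation_mm: tuple[float, float, float]  # (LR, AP, CC)


@dataclass(frozen=True)
class BeamSegment:
    """Beam-on interval between two consecutive control points."""

    t_start: float
    t_end: float
    delta_mu: float
    aperture: Aperture
    gantry_deg: float
    anatomy_state_id: int = -1  # index of the synchronized anatomy state

    def __post_init__(self) -> None:
        if self.delta_mu <= 0:
            raise ValueError("segment delta_mu must be > 0")
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_start < t_end")


@dataclass(frozen=True)
class PlanSegment:
    aperture: Aperture
    gantry_deg: float
    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("plan segment MU must be > 0")


@dataclass(frozen=True)
class TreatmentPlan:
    """Ordered step-and-shoot segments with a per-fraction prescription."""

    segments: tuple[PlanSegment, ...]
    prescription_gy: float

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        if not self.segments:
            raise ValueError("plan needs at least one segment")

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for s in self.segments))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def validate_stream(messages: Sequence[LinacStateMessage]) -> None:
    """Check stream invariants, naming the first offending index."""
    if not messages:
        raise InvalidStreamError("empty stream")
    for i in range(1, len(messages)):
        if messages[i].t <= messages[i - 1].t:
            raise InvalidStreamError(f"non-increasing timestamp at message {i}")
        if messages[i].mu < messages[i - 1].mu - 1e-12:
            raise InvalidStreamError(f"decreasing cumulative MU at message {i}")
        if not messages[i - 1].beam_on and messages[i].mu > messages[i - 1].mu + 1e-9:
            raise InvalidStreamError(
                f"MU advanced across a beam-off interval at message {i}"
            )


def make_segments(messages: Sequence[LinacStateMessage]) -> list[BeamSegment]:
    """Derive beam segments from consecutive control-point pairs.

    A segment is created for every pair whose start message has the beam
    on and whose MU increment is positive.  The interval's aperture and
    gantry angle are those of the start control point.
    """
    validate_stream(messages)
    segments: list[BeamSegment] = []
    for i in range(len(messages) - 1):
        m0, m1 = messages[i], messages[i + 1]
        dmu = m1.mu - m0.mu
        if m0.beam_on and dmu > 0:
            segments.append(
                BeamSegment(
                    t_start=m0.t,
                    t_end=m1.t,
                    delta_mu=dmu,
                    aperture=m0.aperture,
                    gantry_deg=m0.gantry_deg,
                    anatomy_state_id=i,
                )
            )
    return segments


def sync_motion(
    messages: Sequence[LinacStateMessage], motion: Sequence[MotionSample]
) -> np.ndarray:
    """Assign to each message the translation of the nearest motion sample.

    Ties (equidistant samples) resolve to the earlier sample; messages
    beyond the end of the motion stream hold the last sample.  Returns an
    ``(n_messages, 3)`` array of translations in mm.
    """
    if not motion:
        raise ValueError("empty motion stream")
    if not messages:
        raise ValueError("empty message stream")
    mt = np.array([s.t for s in motion])
    if np.any(np.diff(mt) <= 0):
        raise InvalidStreamError("motion timestamps must be strictly increasing")
    trans = np.array([s.translation_mm for s in motion], dtype=float)
    out = np.empty((len(messages), 3))
    for k, msg in enumerate(messages):
        j = int(np.searchsorted(mt, msg.t))          # first sample with t >= msg.t
        if j == 0:
            pick = 0
        elif j == len(mt):
            pick = len(mt) - 1                       # hold last
        else:
            # earlier sample wins ties and equidistance (tolerance guards
            # against float rounding of nominally equidistant stamps)
            pick = j - 1 if msg.t - mt[j - 1] <= mt[j] - msg.t + 1e-9 else j
        out[k] = trans[pick]
    return out


def duty_cycle(messages: Sequence[LinacStateMessage]) -> float:
    """Beam-on time divided by the span from first beam-on to last beam-off.

    Beam state over an interval follows the start control point's flag.
    """
    validate_stream(messages)
    on_time = 0.0
    first_on = None
    last_off = None
    for i in range(len(messages) - 1):
        if messages[i].beam_on:
            t0, t1 = messages[i].t, messages[i + 1].t
            on_time += t1 - t0
            if first_on is None:
                first_on = t0
            last_off = t1
    if first_on is None or last_off is None or last_off <= first_on:
        raise ValueError("stream has no beam-on interval; duty cycle undefined")
    return on_time / (last_off - first_on)


def plan_remaining(plan: TreatmentPlan, delivered_mu: float) -> list[PlanSegment]:
    """Segments of the plan past a delivered-MU cut point.

    The straddled segment is returned with its residual MU; segments
    wholly past the cut are returned intact.  The MU of the remainder
    equals ``total_mu - delivered_mu``.
    """
    total = plan.total_mu
    if delivered_mu < -1e-9 or delivered_mu > total + 1e-9:
        raise ValueError(
            f"delivered_mu={delivered_mu} outside [0, total_mu={total}]"
        )
    remaining: list[PlanSegment] = []
    cum = 0.0
    for seg in plan.segments:
        seg_end = cum + seg.mu
        if seg_end <= delivered_mu + 1e-12:
            pass                                    # fully delivered
        elif cum >= delivered_mu - 1e-12:
            remaining.append(seg)                   # fully remaining
        else:
            residual = seg_end - delivered_mu       # straddled
            if residual > 1e-12:
                remaining.append(replace(seg, mu=residual))
        cum = seg_end
    return remaining


# ---------------------------------------------------------------------------
# serialization (JSONL streams, JSON plans)
# ---------------------------------------------------------------------------


def write_stream_jsonl(messages: Sequence[LinacStateMessage], path) -> None:
    with open(path, "w") as fh:
        for m in messages:
            rec = {
                "t": m.t,
                "gantry_deg": m.gantry_deg,
                "jaws_cm": list(m.aperture.jaws_cm),
                "mlc_cm": [list(m.aperture.mlc_cm[0]), list(m.aperture.mlc_cm[1])],
                "mu": m.mu,
                "beam_on": m.beam_on,
            }
            fh.write(json.dumps(rec) + "\n")


def read_stream_jsonl(path) -> list[LinacStateMessage]:
    messages = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        ap = Aperture(
            tuple(d["jaws_cm"]), (tuple(d["mlc_cm"][0]), tuple(d["mlc_cm"][1]))
        )
        messages.append(
            LinacStateMessage(d["t"], d["gantry_deg"], ap, d["mu"], d["beam_on"])
        )
    return messages


def write_motion_jsonl(motion: Sequence[MotionSample], path) -> None:
    with open(path, "w") as fh:
        for s in motion:
            dx, dy, dz = s.translation_mm
            fh.write(
                json.dumps({"t": s.t, "dx_mm": dx, "dy_mm": dy, "dz_mm": dz}) + "\n"
            )


def read_motion_jsonl(path) -> list[MotionSample]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        out.append(MotionSample(d["t"], (d["dx_mm"], d["dy_mm"], d["dz_mm"])))
    return out


def plan_to_json(plan: TreatmentPlan) -> str:
    doc = {
        "prescription_gy": plan.prescription_gy,
        "total_mu": plan.total_mu,
        "segments": [
            {
                "gantry_deg": s.gantry_deg,
                "jaws_cm": list(s.aperture.jaws_cm),
                "mlc_cm": [list(s.aperture.mlc_cm[0]), list(s.aperture.mlc_cm[1])],
                "leaf_width_cm": s.aperture.leaf_width_cm,
                "mu": s.mu,
            }
            for s in plan.segments
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def write_plan_json(plan: TreatmentPlan, path) -> None:
    Path(path).write_text(plan_to_json(plan))


def read_plan_json(path) -> TreatmentPlan:
    d = json.loads(Path(path).read_text())
    segs = tuple(
        PlanSegment(
            Aperture(
                tuple(s["jaws_cm"]),
                (tuple(s["mlc_cm"][0]), tuple(s["mlc_cm"][1])),
                s.get("leaf_width_cm", 1.0),
            ),
            s["gantry_deg"],
            s["mu"],
        )
        for s in d["segments"]
    )
    return TreatmentPlan(segs, d["prescription_gy"])
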