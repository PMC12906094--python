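"""Delivered-dose accumulation, planned-to-same-MU dose, and forecasting.

The workflow maintains three dose distributions on the reference
(planning) frame:

1. the real-time reconstructed delivered dose — each beam segment is
   computed on the current anatomy (rigidly translated or deformed) and
   mapped back to the reference frame, then summed;
2. the planned dose up to the same MU, ignoring intrafraction motion;
3. the forecast — distribution 1 plus the remainder of the plan
   computed on the latest (frozen) anatomy, with the target's V95%.

Planned and forecast-remainder doses are computed noise free (the live
reconstruction optionally carries the MC-like per-calculation noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import BeamModel, compute_segment_dose
from .grids import Volume
from .registration import DVF, apply_translation, invert_dvf, warp
from .stream import BeamSegment, PlanSegment, TreatmentPlan, plan_remaining


@dataclass
class AnatomyState:
    """Anatomy at a time point: exactly one of a rigid translation or a DVF.

    For a deformable state, ``dvf`` is the pull-back field building the
    current anatomy from the reference (``current = warp(reference,
    dvf)``); ``dvf_inverse`` (the material motion) may be supplied to
    avoid repeated numerical inversion and is computed on demand
    otherwise.
    """

    timestamp: float
    translation_mm: tuple[float, float, float] | None = None
    dvf: DVF | None = None
    dvf_inverse: DVF | None = None
    provenance: str = "motion_stream"

    def __post_init__(self) -> None:
        if (self.translation_mm is None) == (self.dvf is None):
            raise ValueError("exactly one of translation_mm or dvf is required")

    @property
    def is_rigid(self) -> bool:
        return self.translation_mm is not None

    def inverse_field(self) -> DVF:
        if self.dvf is None:
            raise ValueError("rigid state has no DVF")
        if self.dvf_inverse is None:
            self.dvf_inverse = invert_dvf(self.dvf)
        return self.dvf_inverse


@dataclass
class LedgerEntry:
    delta_mu: float
    state_id: int
    seed: int | None


@dataclass
class AccumulatedDose:
    """Running delivered dose on the reference frame with its MU ledger."""

    dose: Volume
    delivered_mu: float = 0.0
    ledger: list[LedgerEntry] = field(default_factory=list)

    @classmethod
    def zeros(cls, reference: Volume) -> "AccumulatedDose":
        return cls(reference.like(np.zeros(reference.shape)))

    def ledger_mu(self) -> float:
        return float(sum(e.delta_mu for e in self.ledger))


@dataclass
class ForecastResult:
    dose: Volume
    mu_at_forecast: float
    v95_pct: float
    wall_time_s: float = 0.0
    timestamp: float = 0.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def reconstruct_segment(
    reference_density: Volume,
    state: AnatomyState,
    segment: BeamSegment,
    model: BeamModel,
    noise_seed=None,
    isocenter=None,
) -> Volume:
    """Segment dose on the reference frame under an anatomy state.

    Rigid: the anatomy is translated, the dose computed, and the result
    counter-translated back.  Deformable: the reference is warped by the
    state's DVF, the dose computed on the current anatomy, and mapped
    back through the inverse DVF.
    """
    if state.is_rigid:
        t = np.asarray(state.translation_mm, dtype=float)
        if not np.any(t):
            return compute_segment_dose(
                reference_density, segment, model,
                noise_seed=noise_seed, isocenter=isocenter,
            )
        moved = apply_translation(reference_density, t, cval=0.0)
        dose = compute_segment_dose(
            moved, segment, model, noise_seed=noise_seed, isocenter=isocenter
        )
        return apply_translation(dose, -t, cval=0.0)

    current = warp(reference_density, state.dvf)
    dose = compute_segment_dose(
        current, segment, model, noise_seed=noise_seed, isocenter=isocenter
    )
    return warp(dose, state.inverse_field())


def accumulate(
    prior: AccumulatedDose,
    segment_dose: Volume,
    delta_mu: float,
    state_id: int = -1,
    seed: int | None = None,
    allow_zero_mu: bool = False,
) -> AccumulatedDose:
    """Add one reconstructed segment to the running delivered dose."""
    if not prior.dose.same_grid(segment_dose):
        raise ValueError("segment dose grid does not match the accumulator")
    if delta_mu < 0 or (delta_mu == 0 and not allow_zero_mu):
        raise ValueError("delta_mu must be positive (zero only for bookkeeping)")
    return AccumulatedDose(
        dose=prior.dose.like(prior.dose.values + segment_dose.values),
        delivered_mu=prior.delivered_mu + delta_mu,
        ledger=prior.ledger + [LedgerEntry(delta_mu, state_id, seed)],
    )


def plan_segment_doses(
    plan: TreatmentPlan,
    reference_density: Volume,
    model: BeamModel,
    isocenter=None,
) -> list[Volume]:
    """Noise-free dose of each plan segment on the unmoved reference."""
    clean = model.noiseless()
    return [
        compute_segment_dose(reference_density, _as_beam_segment(s), clean,
                             isocenter=isocenter)
        for s in plan.segments
    ]


def _as_beam_segment(s: PlanSegment) -> BeamSegment:
    return BeamSegment(0.0, 1.0, s.mu, s.aperture, s.gantry_deg)


def planned_to_delivered_mu(
    plan: TreatmentPlan,
    reference_density: Volume,
    mu: float,
    model: BeamModel,
    segment_doses: list[Volume] | None = None,
    isocenter=None,
) -> Volume:
    """Planned dose up to ``mu`` delivered MU (unmoved anatomy, noise free).

    Full segments before the cut contribute entirely; the straddled
    segment scales linearly with its residual MU fraction (the aperture
    is held within a segment).
    """
    total = plan.total_mu
    if mu < -1e-9 or mu > total + 1e-9:
        raise ValueError(f"mu={mu} outside [0, {total}]")
    if segment_doses is None:
        segment_doses = plan_segment_doses(plan, reference_density, model, isocenter)
    out = np.zeros(reference_density.shape)
    cum = 0.0
    for seg, dose in zip(plan.segments, segment_doses):
        seg_end = cum + seg.mu
        if seg_end <= mu + 1e-12:
            out += dose.values
        elif cum < mu:
            out += dose.values * ((mu - cum) / seg.mu)
        cum = seg_end
    return reference_density.like(out)


def calibrate_output(
    model: BeamModel,
    plan: TreatmentPlan,
    reference_density: Volume,
    target_mask: np.ndarray,
    isocenter=None,
) -> BeamModel:
    """Scale the beam output so the mean planned target dose equals the
    prescription."""
    doses = plan_segment_doses(plan, reference_density, model, isocenter)
    total = np.sum([d.values for d in doses], axis=0)
    mean_target = float(total[target_mask].mean())
    if mean_target <= 0:
        raise ValueError("plan delivers no dose to the target; cannot calibrate")
    return model.with_output(model.output_gy_per_mu * plan.prescription_gy / mean_target)


def forecast(
    acc: AccumulatedDose,
    plan: TreatmentPlan,
    latest_state: AnatomyState,
    reference_density: Volume,
    model: BeamModel,
    ctv_mask: np.ndarray,
    *,
    isocenter=None,
    timestamp: float = 0.0,
    wall_time_s: float = 0.0,
) -> ForecastResult:
    """Forecast of the end-of-fraction dose and target coverage.

    The remainder of the plan is computed on the anatomy frozen at
    ``latest_state`` (noise free), mapped back to the reference frame,
    and added to the delivered dose; V95% of the CTV is evaluated
    against the prescription on the reference frame.
    """
    from .metrics import v_threshold

    clean = model.noiseless()
    remainder = plan_remaining(plan, acc.delivered_mu)
    total = acc.dose.values.copy()
    for seg in remainder:
        dose = reconstruct_segment(
            reference_density, latest_state, _as_beam_segment(seg), clean,
            isocenter=isocenter,
        )
        total += dose.values
    vol = acc.dose.like(total)
    v95 = v_threshold(vol, ctv_mask, plan.prescription_gy)
    return ForecastResult(vol, acc.delivered_mu, v95, wall_time_s, timestamp)
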