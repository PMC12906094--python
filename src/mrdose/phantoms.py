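"""Virtual phantoms, plans, streams, motion traces and ground-truth
"measurements".

These generators replace the physical setups of the workflow study: a
diode-array cylinder on a motion platform (time-resolved point dosimetry
under rigid motion), a water-bag-on-slab phantom with a dose film at the
interface (deformable dose accumulation), a prostate-like step-and-shoot
plan, and the three motion traces (static, 10 mm CC linear drift,
patient-like drift with partial recovery).

The ground truth "measurement" is the same analytic engine run noise
free on the true anatomy, optionally with additive readout noise; it is
independent of the reconstruction pipeline under test, which consumes
only the streamed machine state and motion/images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registration as reg
from .engine import BeamModel, compute_segment_dose
from .grids import Volume, grid_points
from .registration import DVF, invert_dvf, warp
from .stream import (
    Aperture,
    BeamSegment,
    LinacStateMessage,
    MotionSample,
    PlanSegment,
    TreatmentPlan,
    make_segments,
    sync_motion,
)

AIR_DENSITY = 0.0012
WATER_DENSITY = 1.0
WEM_DENSITY = 1.02
MARKER_DENSITY = 1.1


@dataclass
class DiodeArraySpec:
    """Point detectors on two orthogonal interior planes of a phantom."""

    positions_mm: np.ndarray          # (N, 3)
    ids: list[str]
    readout_rate_hz: float = 40.0

    def __post_init__(self) -> None:
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        if len(self.ids) != len(self.positions_mm):
            raise ValueError("one id per diode required")
        uniq = {tuple(np.round(p, 6)) for p in self.positions_mm}
        if len(uniq) != len(self.positions_mm):
            raise ValueError("diode positions must be distinct")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "diode_id": self.ids,
                "x_mm": self.positions_mm[:, 0],
                "y_mm": self.positions_mm[:, 1],
                "z_mm": self.positions_mm[:, 2],
            }
        ).to_csv(path, index=False)


@dataclass
class FilmPlaneSpec:
    """A rectangular film at a horizontal plane y = y_mm."""

    y_mm: float
    x_range_mm: tuple[float, float] = (-25.0, 25.0)
    z_range_mm: tuple[float, float] = (-50.0, 50.0)
    pixel_mm: float = 2.0

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.arange(self.x_range_mm[0], self.x_range_mm[1] + 1e-9, self.pixel_mm)
        z = np.arange(self.z_range_mm[0], self.z_range_mm[1] + 1e-9, self.pixel_mm)
        return x, z

    def points(self) -> np.ndarray:
        """(N, 3) reference-frame film pixel centres."""
        x, z = self.grid()
        X, Z = np.meshgrid(x, z, indexing="ij")
        return np.stack([X.ravel(), np.full(X.size, self.y_mm), Z.ravel()], axis=1)

    @property
    def map_shape(self) -> tuple[int, int]:
        x, z = self.grid()
        return len(x), len(z)


@dataclass
class MotionTrace:
    """Rigid translations of the anatomy sampled at a fixed rate."""

    kind: str
    samples: list[MotionSample]
    params: dict = field(default_factory=dict)

    def translations(self) -> np.ndarray:
        return np.array([s.translation_mm for s in self.samples])


@dataclass
class DeformationScenario:
    """Piecewise-constant deformation epochs for the film phantom.

    Each epoch starts at ``start_times_s[k]`` and carries the anatomy's
    forward material motion ``motions[k]`` (a DVF; material point p moves
    to ``p + m(p)``).  Epoch 0 is the reference state (zero motion).
    """

    start_times_s: list[float]
    motions: list[DVF | None]       # None = identity

    def epoch_at(self, t: float) -> int:
        k = int(np.searchsorted(self.start_times_s, t, side="right") - 1)
        return max(k, 0)


@dataclass
class Phantom:
    density: Volume
    image: Volume
    masks: dict[str, np.ndarray]
    diodes: DiodeArraySpec | None = None
    film: FilmPlaneSpec | None = None

    @property
    def isocenter(self) -> np.ndarray:
        return self.density.center


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _centered_volume(shape, spacing) -> Volume:
    shape = tuple(int(s) for s in shape)
    spacing = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
    origin = tuple(-0.5 * sp * (n - 1) for sp, n in zip(spacing, shape))
    return Volume(np.zeros(shape), spacing, origin)


def build_phantom(
    kind: str,
    shape=(64, 64, 64),
    spacing=3.0,
    seed: int = 0,
    **params,
) -> Phantom:
    """Construct a named phantom geometry (isocenter at the grid centre).

    Kinds: ``water_cylinder`` (homogeneous cylinder along CC),
    ``delta4_like`` (cylinder with diode lattices on two orthogonal
    planes and a spherical CTV in the high-dose core), and
    ``waterbag_film`` (water on a water-equivalent slab with a film at
    the interface and two fiducial markers at the film ends).
    """
    base = _centered_volume(shape, spacing)
    X, Y, Z = grid_points(base)
    air = params.get("air_density", AIR_DENSITY)
    extent = np.array(base.shape) * np.array(base.spacing)

    if kind == "water_cylinder":
        radius = params.get("radius_mm", 80.0)
        if radius > min(extent[0], extent[1]) / 2:
            raise ValueError("cylinder radius exceeds grid bounds")
        inside = np.broadcast_to((X**2 + Y**2) <= radius**2, base.shape)
        density = np.where(inside, WATER_DENSITY, air)
        image = np.where(inside, 1.0, 0.05)
        return Phantom(base.like(density), base.like(image), {"body": inside.copy()})

    if kind == "delta4_like":
        radius = params.get("radius_mm", 85.0)
        half_len = params.get("half_length_mm", 85.0)
        lattice = params.get("lattice_mm", 5.0)
        lattice_extent = params.get("lattice_extent_mm", 50.0)
        ctv_radius = params.get("ctv_radius_mm", 15.0)
        if radius > min(extent[0], extent[1]) / 2 or half_len > extent[2] / 2:
            raise ValueError("phantom geometry exceeds grid bounds")
        inside = ((X**2 + Y**2) <= radius**2) & (np.abs(Z) <= half_len)
        density = np.where(inside, WATER_DENSITY, air)
        image = np.where(inside, 1.0, 0.05)
        ctv = (X**2 + Y**2 + Z**2) <= ctv_radius**2

        g = np.arange(-lattice_extent, lattice_extent + 1e-9, lattice)
        pts, ids = [], []
        for a in g:                         # coronal plane y = 0
            for b in g:
                pts.append((a, 0.0, b))
                ids.append(f"cor_{a:+.0f}_{b:+.0f}")
        for a in g:                         # sagittal plane x = 0
            if abs(a) < 1e-9:
                continue                    # intersection line already covered
            for b in g:
                pts.append((0.0, a, b))
                ids.append(f"sag_{a:+.0f}_{b:+.0f}")
        pts_arr = np.array(pts)
        keep = (pts_arr[:, 0] ** 2 + pts_arr[:, 1] ** 2 <= radius**2) & (
            np.abs(pts_arr[:, 2]) <= half_len
        )
        diodes = DiodeArraySpec(
            pts_arr[keep], [i for i, k in zip(ids, keep) if k],
            readout_rate_hz=params.get("readout_rate_hz", 40.0),
        )
        return Phantom(
            base.like(density),
            base.like(image),
            {"body": inside + np.zeros_like(density, bool), "ctv": ctv},
            diodes=diodes,
        )

    if kind == "waterbag_film":
        interface_y = params.get("interface_y_mm", -24.0)
        water_top = params.get("water_top_mm", 42.0)
        slab_bottom = params.get("slab_bottom_mm", -63.0)
        half_width = params.get("half_width_mm", 75.0)
        film = FilmPlaneSpec(
            y_mm=interface_y,
            pixel_mm=params.get("film_pixel_mm", 2.0),
        )
        lateral = (np.abs(X) <= half_width) & (np.abs(Z) <= half_width)
        water = lateral & (Y > interface_y) & (Y <= water_top)
        slab = lateral & (Y <= interface_y) & (Y >= slab_bottom)
        density = np.where(water, WATER_DENSITY, np.where(slab, WEM_DENSITY, air))

        # MR-like image channel: water bright, slab mid, air dark, plus a
        # gentle smooth intensity modulation standing in for coil/signal
        # inhomogeneity (gives the registrar gradients away from edges).
        image = np.where(water, 1.0, np.where(slab, 0.55, 0.05))
        mod = 0.04 * (
            np.sin(2 * np.pi * X / 55.0)
            + np.sin(2 * np.pi * Y / 47.0)
            + np.sin(2 * np.pi * Z / 61.0)
        )
        image = image * (1.0 + mod)
        # fiducial markers (fish-oil-like) at the film ends, bright in MR
        marker_r = params.get("marker_radius_mm", 4.0)
        for zc in (film.z_range_mm[0] - 4.0, film.z_range_mm[1] + 4.0):
            m = (X**2 + (Y - (interface_y + 3.0)) ** 2 + (Z - zc) ** 2) <= marker_r**2
            image = np.where(m, 1.6, image)
            density = np.where(m, MARKER_DENSITY, density)

        film_band = (
            lateral
            & (np.abs(Y - interface_y) <= base.spacing[1])
            & (np.abs(X) <= film.x_range_mm[1])
            & (np.abs(Z) <= film.z_range_mm[1])
        )
        return Phantom(
            base.like(density),
            base.like(image),
            {"water": water, "slab": slab, "film_band": film_band},
            film=film,
        )

    raise ValueError(f"unknown phantom kind: {kind!r}")


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------


def make_plan(
    n_segments: int,
    field_size_cm: float = 7.0,
    prescription_gy: float = 7.5,
    seed: int = 0,
    *,
    total_mu: float | None = None,
    target_radius_mm: float = 15.0,
    margin_mm: float = 14.0,
    n_leaf_pairs: int = 16,
    leaf_width_cm: float = 1.0,
) -> TreatmentPlan:
    """A step-and-shoot plan, reproducible under ``seed``.

    A single segment yields an open ``field_size_cm`` square at gantry 0
    (the deformable-test beam).  Multiple segments get evenly spaced
    gantry angles and conformal-ish MLC openings around a spherical
    target of ``target_radius_mm`` plus ``margin_mm``, with small seeded
    per-leaf jitter emulating IMRT modulation.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if field_size_cm <= 0:
        raise ValueError("field size must be positive")
    rng = np.random.default_rng(seed)
    total = float(total_mu) if total_mu is not None else 25.0 * n_segments

    if n_segments == 1:
        ap = Aperture.open_field(field_size_cm, field_size_cm,
                                 n_pairs=n_leaf_pairs, leaf_width_cm=leaf_width_cm)
        return TreatmentPlan((PlanSegment(ap, 0.0, total),), prescription_gy)

    weights = 0.7 + 0.6 * rng.random(n_segments)
    mus = np.round(total * weights / weights.sum(), 3)
    mus[-1] = np.round(total - mus[:-1].sum(), 3)

    r_cm = target_radius_mm / 10.0
    m_cm = margin_mm / 10.0
    jaw_u = min(field_size_cm / 2.0, r_cm + m_cm + 0.5)
    jaw_v = min(field_size_cm / 2.0, r_cm + m_cm + 0.5)
    strips = None
    segs = []
    for k in range(n_segments):
        gantry = (360.0 * k / n_segments) % 360.0
        bank_a, bank_b = [], []
        ap0 = Aperture.open_field(field_size_cm, field_size_cm,
                                  n_pairs=n_leaf_pairs, leaf_width_cm=leaf_width_cm)
        strips = ap0.leaf_strips_cm()
        for i in range(n_leaf_pairs):
            v_c = 0.5 * (strips[i, 0] + strips[i, 1])
            if abs(v_c) <= r_cm + m_cm:
                half = np.sqrt(max(r_cm**2 - min(abs(v_c), r_cm) ** 2, 0.0)) + m_cm
                ja = float(np.round(rng.uniform(-0.2, 0.2), 3))
                jb = float(np.round(rng.uniform(-0.2, 0.2), 3))
                a = max(-jaw_u, -half + ja)
                b = min(jaw_u, half + jb)
                if b - a < 0.5:             # keep a minimal opening
                    a, b = -0.25, 0.25
                bank_a.append(round(a, 3))
                bank_b.append(round(b, 3))
            else:
                bank_a.append(0.0)
                bank_b.append(0.0)
        ap = Aperture(
            (-jaw_u, jaw_u, -jaw_v, jaw_v),
            (tuple(bank_a), tuple(bank_b)),
            leaf_width_cm,
        )
        segs.append(PlanSegment(ap, gantry, float(mus[k])))
    return TreatmentPlan(tuple(segs), prescription_gy)


# ---------------------------------------------------------------------------
# stream generation
# ---------------------------------------------------------------------------


def gen_stream(
    plan: TreatmentPlan,
    dose_rate_mu_per_min: float = 420.0,
    msg_rate_hz: float = 5.0,
    beam_holds: list[tuple[float, float]] | None = None,
    inter_segment_hold_s: float = 0.4,
    start_time: float = 0.0,
) -> list[LinacStateMessage]:
    """Simulate the 5 Hz control-point stream delivering a plan.

    Cumulative MU rises at the dose rate while the beam is on and clamps
    exactly at each plan-segment boundary (the beam holds for
    ``inter_segment_hold_s`` while the leaves travel, as a step-and-shoot
    linac does); ``beam_holds`` adds external beam-off windows.  The
    final message carries exactly the plan's total MU with the beam off.
    """
    if dose_rate_mu_per_min <= 0 or dose_rate_mu_per_min > 420.0 + 1e-9:
        raise ValueError("dose rate must lie in (0, 420] MU/min")
    if msg_rate_hz <= 0:
        raise ValueError("message rate must be positive")
    holds = beam_holds or []
    dt = 1.0 / msg_rate_hz
    rate = dose_rate_mu_per_min / 60.0

    messages: list[LinacStateMessage] = []
    seg_idx = 0
    mu_done = 0.0                       # MU of completed segments
    mu_in_seg = 0.0
    hold_until = -np.inf
    t = start_time
    guard = 0
    while seg_idx < len(plan.segments):
        guard += 1
        if guard > 10_000_000:
            raise RuntimeError("stream generation did not terminate")
        seg = plan.segments[seg_idx]
        in_hold = t < hold_until - 1e-12 or any(
            h0 - 1e-12 <= t < h1 - 1e-12 for h0, h1 in holds
        )
        beam_on = not in_hold
        messages.append(
            LinacStateMessage(
                t=round(t, 6),
                gantry_deg=seg.gantry_deg,
                aperture=seg.aperture,
                mu=mu_done + mu_in_seg,
                beam_on=beam_on,
            )
        )
        if beam_on:
            mu_in_seg += rate * dt
            if mu_in_seg >= seg.mu - 1e-12:
                mu_in_seg = seg.mu          # clamp at the boundary
                mu_done += seg.mu
                mu_in_seg = 0.0
                seg_idx += 1
                if seg_idx < len(plan.segments) and inter_segment_hold_s > 0:
                    hold_until = t + dt + inter_segment_hold_s
        t += dt
    last = plan.segments[-1]
    messages.append(
        LinacStateMessage(
            t=round(t, 6), gantry_deg=last.gantry_deg, aperture=last.aperture,
            mu=mu_done, beam_on=False,
        )
    )
    return messages


# ---------------------------------------------------------------------------
# motion traces
# ---------------------------------------------------------------------------


def gen_motion(
    kind: str,
    duration_s: float,
    rate_hz: float = 5.0,
    *,
    amplitude_mm: float = 10.0,
    apex_mm: float = 8.0,
    return_to_mm: float = 2.0,
    apex_frac: float = 0.45,
    seed: int | None = None,
) -> MotionTrace:
    """Generate a rigid motion trace in the CC direction.

    ``static`` — all zeros; ``linear_drift`` — CC rises linearly from 0
    to ``amplitude_mm`` (default 10 mm, the drift scenario);
    ``patient_like`` — piecewise-linear rise to ``apex_mm`` at
    ``apex_frac`` of the duration, then partial recovery to
    ``return_to_mm`` (the qualitative shape of the patient-derived
    prostate drift: coverage drops, then largely recovers).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration_s + 1e-9, 1.0 / rate_hz)
    cc = np.zeros_like(t)
    params: dict = {"duration_s": duration_s, "rate_hz": rate_hz}
    if kind == "static":
        pass
    elif kind == "linear_drift":
        cc = amplitude_mm * t / duration_s
        params["amplitude_mm"] = amplitude_mm
    elif kind == "patient_like":
        ta = apex_frac * duration_s
        rise = t <= ta
        cc[rise] = apex_mm * t[rise] / ta
        cc[~rise] = apex_mm + (return_to_mm - apex_mm) * (t[~rise] - ta) / (
            duration_s - ta
        )
        params.update(apex_mm=apex_mm, return_to_mm=return_to_mm, apex_frac=apex_frac)
    else:
        raise ValueError(f"unknown motion kind: {kind!r}")
    samples = [MotionSample(float(ti), (0.0, 0.0, float(ci))) for ti, ci in zip(t, cc)]
    return MotionTrace(kind, samples, params)


# ---------------------------------------------------------------------------
# deformation: smooth ridge field ("roll under the water bag")
# ---------------------------------------------------------------------------


def roll_dvf(
    grid: Volume,
    center_mm: tuple[float, float],
    amplitude_mm: float,
    width_mm: float,
    direction=(0.0, 1.0, 0.0),
    margin_mm: float = 12.0,
) -> DVF:
    """Smooth ridge displacement emulating a roll pushed under the setup.

    The displacement points along ``direction`` (default +y, upward) with
    profile ``A * exp(-((y-cy)^2 + (z-cz)^2) / width^2)`` — constant
    along the roll axis (x), maximal (= ``amplitude_mm``) at the crest,
    below 1% of the amplitude beyond 3 widths, and tapered to zero within
    ``margin_mm`` of the grid boundary.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    cy, cz = center_mm
    X, Y, Z = grid_points(grid)
    profile = np.exp(-(((Y - cy) ** 2) + (Z - cz) ** 2) / width_mm**2)

    def _taper(c: np.ndarray, axis: int) -> np.ndarray:
        lo = grid.axis_coords(axis)[0]
        hi = grid.axis_coords(axis)[-1]
        d = np.minimum(c - lo, hi - c)
        w = np.clip(d / margin_mm, 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * w)

    taper = _taper(X, 0) * _taper(Y, 1) * _taper(Z, 2)
    disp = np.zeros((3, *grid.shape))
    dirv = np.asarray(direction, dtype=float)
    dirv = dirv / np.linalg.norm(dirv)
    for a in range(3):
        disp[a] = amplitude_mm * dirv[a] * profile * taper
    return DVF(disp, grid.spacing, grid.origin)


def make_roll_scenario(
    phantom: Phantom,
    pause_times_s: tuple[float, float],
    amplitude_mm: float = 8.0,
    width_mm: float = 22.0,
    centers_z_mm: tuple[float, float] = (-18.0, 18.0),
) -> DeformationScenario:
    """Roll placed under the water bag at two pause points.

    Epoch 0 is the reference anatomy; epochs 1 and 2 carry the ridge
    motion at two different CC positions, centred vertically at the film
    interface so the film itself deforms.
    """
    if phantom.film is None:
        raise ValueError("roll scenario needs a film phantom")
    cy = phantom.film.y_mm
    motions: list[DVF | None] = [None]
    for cz in centers_z_mm:
        motions.append(roll_dvf(phantom.density, (cy, cz), amplitude_mm, width_mm))
    return DeformationScenario([0.0, *pause_times_s], motions)


def scenario_states(scenario: DeformationScenario):
    """Per-epoch (warp_field, inverse) pairs for anatomy construction.

    The forward material motion ``m`` moves material point p to p + m(p);
    the current anatomy image is ``warp(reference, invert(m))`` and the
    dose computed on it maps back to the reference frame by warping with
    ``m`` itself.  Returns a list of ``(u, u_inv)`` with ``u`` the warp
    field building the current anatomy and ``u_inv`` its inverse (= m).
    """
    out = []
    for m in scenario.motions:
        if m is None:
            out.append((None, None))
        else:
            out.append((invert_dvf(m), m))
    return out


# ---------------------------------------------------------------------------
# ground-truth virtual measurement
# ---------------------------------------------------------------------------


def virtual_measurement_rigid(
    phantom: Phantom,
    messages: list[LinacStateMessage],
    trace: MotionTrace,
    model: BeamModel,
    noise_sd_gy: float = 0.0,
    noise_seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Time-resolved diode readings under the true rigid motion.

    Runs the engine noise free on the true (translated) anatomy for each
    beam segment and samples the reference-frame dose at the diode
    positions.  Returns a 40 Hz long-format readout DataFrame
    (``t, diode_id, dose_gy``), the per-segment cumulative diode dose
    matrix ``(n_segments, n_diodes)``, and the segment-end MU axis.
    """
    from .accumulation import AnatomyState, reconstruct_segment

    if phantom.diodes is None:
        raise ValueError("rigid measurement needs a diode array")
    segments = make_segments(messages)
    translations = sync_motion(messages, trace.samples)
    clean = model.noiseless()
    n_d = len(phantom.diodes.positions_mm)
    cum = np.zeros((len(segments), n_d))
    running = np.zeros(n_d)
    for k, seg in enumerate(segments):
        state = AnatomyState(seg.t_start, translation_mm=tuple(translations[seg.anatomy_state_id]))
        dose = reconstruct_segment(phantom.density, state, seg, clean)
        running = running + dose.sample(phantom.diodes.positions_mm)
        cum[k] = running
    mu_axis = np.cumsum([s.delta_mu for s in segments])

    # resample cumulative readings to the diode readout rate
    t_end = np.array([s.t_end for s in segments])
    rate = phantom.diodes.readout_rate_hz
    duration = messages[-1].t - messages[0].t
    t_read = messages[0].t + np.arange(int(np.ceil(duration * rate))) / rate
    rows = []
    rng = np.random.default_rng(noise_seed)
    for j in range(n_d):
        series = np.interp(t_read, t_end, cum[:, j], left=0.0)
        if noise_sd_gy > 0:
            series = series + rng.normal(0.0, noise_sd_gy, series.shape)
        rows.append(
            pd.DataFrame(
                {"t": t_read, "diode_id": phantom.diodes.ids[j], "dose_gy": series}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    return df, cum, mu_axis


def virtual_measurement_film(
    phantom: Phantom,
    messages: list[LinacStateMessage],
    scenario: DeformationScenario,
    model: BeamModel,
    states=None,
) -> np.ndarray:
    """Film-plane dose map accumulated at the moving film material points.

    For each beam segment the engine runs noise free on the true current
    anatomy of the segment's epoch; the dose is sampled at the deformed
    positions of the film pixels (material points move with the
    anatomy).  Returns the film dose map with shape ``film.map_shape``.
    """
    if phantom.film is None:
        raise ValueError("film measurement needs a film plane")
    segments = make_segments(messages)
    if states is None:
        states = scenario_states(scenario)
    p_ref = phantom.film.points()

    # current anatomies and deformed film points, one per epoch
    epoch_cache: dict[int, tuple[Volume, np.ndarray]] = {}
    for e, (u, u_inv) in enumerate(states):
        if u is None:
            epoch_cache[e] = (phantom.density, p_ref)
        else:
            cur = warp(phantom.density, u)
            m = u_inv  # forward material motion
            disp = np.stack(
                [
                    Volume(m.disp[a], m.spacing, m.origin).sample(p_ref)
                    for a in range(3)
                ],
                axis=1,
            )
            epoch_cache[e] = (cur, p_ref + disp)

    clean = model.noiseless()
    film = np.zeros(len(p_ref))
    for seg in segments:
        e = scenario.epoch_at(seg.t_start)
        cur, p_cur = epoch_cache[min(e, len(states) - 1)]
        dose = compute_segment_dose(cur, seg, clean)
        film = film + dose.sample(p_cur)
    return film.reshape(phantom.film.map_shape)
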