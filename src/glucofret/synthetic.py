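"""Ground-truth glucose kinetics, sensor response, and movie rendering.

No raw movies accompany the study this package models, so every
downstream stage is exercised on synthetic data with known ground truth.
Three layers are simulated:

**Kinetics.**  Intracellular free glucose G(t) follows a minimal
single-pool model with one knob per pathway of the neuronal glucose
network (facilitated uptake, hexokinase-gated consumption by glycolysis,
the pentose phosphate shunt, and a transient hexosamine flux)::

    dG/dt = v_t * (Gext/(Kt+Gext) - G/(Kt+G))            (symmetric carrier)
          - gate_HK(t) * [v_gly + v_ppp * ppp_on(t) + v_hbp(t)] * G/(Kc+G)

Glycolysis blockade (IAA) causes glucose-6-phosphate build-up that
progressively inhibits hexokinase: ``gate_HK`` relaxes from 1 to 0 with
time constant ``tau_hk_inhibition`` after IAA onset, producing the
delayed glucose accumulation seen experimentally.  In the Alzheimer-model
genotype (3xTgAD) IAA also discloses a transient hexosamine-pathway flux
(``v_hbp_max`` decaying with ``tau_hbp_transient``), giving the biphasic
dip-then-rise response; its scale is zero in non-transgenic cells.
6-AN removes the pentose phosphate term.  Genotype differences enter
only through non-negative scale factors on the pathway fluxes.

**Sensor.**  The FRET ratio follows a saturating one-site binding curve
``R(G) = r_min + (r_max - r_min) * G/(Kd + G)``; only relative ratio
changes matter downstream, so ``r_min``/``r_max`` are conventions.

**Rendering.**  Cells are drawn as soft-edged ellipses (dimmed nuclei)
on a dark background.  The acceptor image is the donor image times each
cell's ratio, so noise-free and drift-free the ROI-mean ratio equals
ground truth exactly.  Corruptions — per-channel linear photobleaching,
x-y stage drift, intensity-proportional Gaussian photon noise, and
transient defocus artifacts — are injected with known parameters and
returned so recovery can be tested.  A single integer seed drives all
randomness through named substreams.

Default kinetic and sensor parameters ship in ``data/default_params.yaml``;
they are calibrated so that non-transgenic defaults give roughly a
-2 %/min relative-ratio slope 2-7 min into glucose restriction and about
+10% after 50 min of a 2.5 -> 10 mM step.  Calibration values are
defaults, not claims about any real dataset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
import yaml
from scipy.optimize import brentq

from .imaging import RoiMask, TwoChannelStack

__all__ = [
    "ProtocolEvent",
    "Protocol",
    "KineticParams",
    "SensorParams",
    "Ellipse",
    "CellSpec",
    "SceneParams",
    "GlucoseTrace",
    "RenderTruth",
    "default_params",
    "simulate_glucose",
    "steady_state_glucose",
    "sensor_ratio",
    "simulate_cell_ratio",
    "render_movie",
    "default_scene",
    "standard_protocols",
]

GENOTYPES = ("nonTg", "3xTgAD")


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolEvent:
    """Superfusion condition taking effect at ``time_min``."""

    time_min: float
    glucose_mM: float
    iaa: bool = False
    six_an: bool = False


@dataclass(frozen=True)
class Protocol:
    """Timed extracellular conditions driving simulation and analysis.

    The first event must sit at t = 0 and defines the baseline
    condition; subsequent events switch bath glucose and/or inhibitors.
    """

    events: tuple[ProtocolEvent, ...]
    duration_min: float
    sample_interval_s: float = 15.0

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("protocol needs at least one event")
        times = [e.time_min for e in self.events]
        if times[0] != 0:
            raise ValueError("first event must be at t = 0 (baseline)")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times[-1] > self.duration_min:
            raise ValueError("events must lie within [0, duration]")
        if any(e.glucose_mM < 0 for e in self.events):
            raise ValueError("extracellular glucose must be non-negative")
        if self.sample_interval_s <= 0:
            raise ValueError("sample interval must be positive")

    def sample_times_min(self) -> np.ndarray:
        dt = self.sample_interval_s / 60.0
        n = int(np.floor(self.duration_min / dt + 1e-9)) + 1
        return np.arange(n) * dt

    def event_at(self, t_min: float) -> ProtocolEvent:
        current = self.events[0]
        for e in self.events:
            if e.time_min <= t_min + 1e-12:
                current = e
            else:
                break
        return current

    @property
    def stimulus_time_min(self) -> float | None:
        """Time of the first condition change after baseline, if any."""
        return self.events[1].time_min if len(self.events) > 1 else None

    def onset_time(self, which: str) -> float | None:
        """First time IAA ('iaa') or 6-AN ('six_an') switches on."""
        for e in self.events:
            if getattr(e, which):
                return e.time_min
        return None

    def to_dict(self) -> dict:
        return {
            "duration_min": self.duration_min,
            "sample_interval_s": self.sample_interval_s,
            "events": [
                {"time_min": e.time_min, "glucose_mM": e.glucose_mM,
                 "iaa": e.iaa, "six_an": e.six_an}
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            events=tuple(ProtocolEvent(**e) for e in d["events"]),
            duration_min=d["duration_min"],
            sample_interval_s=d.get("sample_interval_s", 15.0),
        )


def standard_protocols(baseline_glucose_mM: float = 2.5) -> dict[str, Protocol]:
    """The five named superfusion protocols used throughout.

    Each starts with a 10 min baseline at 2.5 mM extracellular glucose:

    - ``step10``: step to 10 mM for 50 min (uptake assay)
    - ``restriction``: step to 0.2 mM for 30 min (elimination assay)
    - ``iaa``: glycolysis inhibition (200 uM IAA) for 30 min
    - ``six_an``: pentose-phosphate inhibition (6-AN) for 30 min
    - ``combined``: IAA and 6-AN together for 30 min
    """
    g = baseline_glucose_mM
    base = ProtocolEvent(0.0, g)
    return {
        "step10": Protocol((base, ProtocolEvent(10.0, 10.0)), duration_min=60.0),
        "restriction": Protocol((base, ProtocolEvent(10.0, 0.2)), duration_min=40.0),
        "iaa": Protocol((base, ProtocolEvent(10.0, g, iaa=True)), duration_min=40.0),
        "six_an": Protocol((base, ProtocolEvent(10.0, g, six_an=True)),
                           duration_min=40.0),
        "combined": Protocol((base, ProtocolEvent(10.0, g, iaa=True, six_an=True)),
                             duration_min=40.0),
    }


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Transport/consumption fluxes (mM/min), saturation constants (mM),
    gating time constants (min) and genotype scale factors."""

    v_transport: float
    k_transport: float
    v_glycolysis: float
    v_ppp: float
    v_hbp_max: float
    k_consume: float
    tau_hk_inhibition: float
    tau_hbp_transient: float
    genotype: str = "nonTg"
    glycolysis_scale: float = 1.0
    ppp_scale: float = 1.0
    hbp_transient_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        for name in (
            "v_transport", "k_transport", "v_glycolysis", "v_ppp", "v_hbp_max",
            "k_consume", "tau_hk_inhibition", "tau_hbp_transient",
            "glycolysis_scale", "ppp_scale", "hbp_transient_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SensorParams:
    """One-site binding ratio response: half-saturation and ratio bounds."""

    k_d: float = 0.7
    r_min: float = 1.0
    r_max: float = 2.0

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("require r_max > r_min > 0")
        if self.k_d <= 0:
            raise ValueError("k_d must be positive")


def default_params(genotype: str = "nonTg") -> tuple[KineticParams, SensorParams]:
    """Calibrated default kinetic and sensor parameters for a genotype."""
    raw = yaml.safe_load(
        resources.files("glucofret.data").joinpath("default_params.yaml").read_text()
    )
    kin = dict(raw["kinetics"])
    scales = kin.pop("genotypes")[genotype]
    kinetic = KineticParams(genotype=genotype, **kin, **scales)
    sensor = SensorParams(**raw["sensor"])
    return kinetic, sensor


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlucoseTrace:
    """Ground-truth intracellular glucose series (minutes -> mM)."""

    time_min: np.ndarray
    glucose_mM: np.ndarray


def _fluxes(params: KineticParams, g: float, gext: float,
            hk_gate: float, ppp_on: float, hbp_flux: float) -> float:
    kt = params.k_transport
    transport = params.v_transport * (gext / (kt + gext) - g / (kt + g))
    demand = (
        params.v_glycolysis * params.glycolysis_scale
        + params.v_ppp * params.ppp_scale * ppp_on
        + hbp_flux
    )
    consumption = hk_gate * demand * g / (params.k_consume + g)
    return transport - consumption


def simulate_glucose(
    params: KineticParams,
    protocol: Protocol,
    g0: float,
    internal_step_s: float = 1.0,
) -> GlucoseTrace:
    """Integrate the glucose model over a protocol.

    Fixed-step RK4 at a 1 s internal step (the dynamics are far from
    stiff at physiological rates, and a fixed step guarantees
    determinism), resampled onto the protocol's sampling grid.  The
    internal grid includes every event time so no step straddles a
    condition change.
    """
    if g0 < 0:
        raise ValueError("g0 must be non-negative")

    t_iaa = protocol.onset_time("iaa")
    t_6an = protocol.onset_time("six_an")

    def rhs(t: float, g: float) -> float:
        ev = protocol.event_at(t)
        hk_gate = 1.0
        hbp = 0.0
        if t_iaa is not None and t >= t_iaa and ev.iaa:
            dt = t - t_iaa
            hk_gate = float(np.exp(-dt / params.tau_hk_inhibition)) \
                if params.tau_hk_inhibition > 0 else 0.0
            hbp = params.v_hbp_max * params.hbp_transient_scale * (
                float(np.exp(-dt / params.tau_hbp_transient))
                if params.tau_hbp_transient > 0 else 0.0
            )
        ppp_on = 0.0 if (t_6an is not None and t >= t_6an and ev.six_an) else 1.0
        return _fluxes(params, max(g, 0.0), ev.glucose_mM, hk_gate, ppp_on, hbp)

    # fine grid: uniform internal step plus all event times
    dt_int = internal_step_s / 60.0
    fine = np.arange(0.0, protocol.duration_min + dt_int / 2, dt_int)
    event_times = np.array([e.time_min for e in protocol.events])
    fine = np.unique(np.concatenate([fine, event_times,
                                     [protocol.duration_min]]))

    # in the exact model dG/dt < 0 whenever G exceeds both the bath and the
    # start value, so this bound can only be crossed by numerical instability
    g_bound = 1.1 * max(g0, max(e.glucose_mM for e in protocol.events)) + 1.0

    g = float(g0)
    g_fine = np.empty(len(fine))
    g_fine[0] = g
    for i in range(1, len(fine)):
        t0, t1 = fine[i - 1], fine[i]
        h = t1 - t0
        k1 = rhs(t0, g)
        k2 = rhs(t0 + h / 2, g + h * k1 / 2)
        k3 = rhs(t0 + h / 2, g + h * k2 / 2)
        k4 = rhs(t1, g + h * k3)
        g = g + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(g) or g > g_bound:
            raise RuntimeError(
                f"glucose integration unstable at t = {t1:.3f} min; "
                "parameter magnitudes exceed what the fixed internal step "
                "can resolve"
            )
        g = max(g, 0.0)
        g_fine[i] = g

    t_out = protocol.sample_times_min()
    g_out = np.interp(t_out, fine, g_fine)
    return GlucoseTrace(time_min=t_out, glucose_mM=g_out)


def steady_state_glucose(params: KineticParams, gext: float) -> float:
    """Baseline fixed point of the model (no inhibitors).

    Influx decreases and consumption increases monotonically in G, so
    the balance has a unique root in [0, gext].
    """
    if gext < 0:
        raise ValueError("gext must be non-negative")

    def f(g: float) -> float:
        return _fluxes(params, g, gext, hk_gate=1.0, ppp_on=1.0, hbp_flux=0.0)

    if gext == 0 or f(0.0) <= 0:
        return 0.0
    if f(gext) >= 0:  # no consumption: equilibrates with the bath
        return gext
    return float(brentq(f, 0.0, gext, xtol=1e-12))


# ---------------------------------------------------------------------------
# sensor
# ---------------------------------------------------------------------------

def sensor_ratio(g, sensor: SensorParams):
    """FRET ratio for glucose concentration(s) ``g`` (mM).

    Monotone increasing, r_min at zero glucose, approaching r_max at
    saturation; vectorized over array input.
    """
    garr = np.asarray(g, dtype=float)
    if np.any(garr < 0):
        raise ValueError("glucose concentration must be non-negative")
    r = sensor.r_min + (sensor.r_max - sensor.r_min) * garr / (sensor.k_d + garr)
    return float(r) if np.isscalar(g) else r


def simulate_cell_ratio(
    params: KineticParams,
    sensor: SensorParams,
    protocol: Protocol,
    g0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth ratio series for one cell: (time_min, ratio).

    When ``g0`` is omitted the cell starts at its baseline steady state
    for the protocol's initial bath glucose.
    """
    if g0 is None:
        g0 = steady_state_glucose(params, protocol.events[0].glucose_mM)
    trace = simulate_glucose(params, protocol, g0)
    return trace.time_min, sensor_ratio(trace.glucose_mM, sensor)


# ---------------------------------------------------------------------------
# scene description and rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (x = column, y = row)."""

    cx: float
    cy: float
    rx: float
    ry: float

    def radial(self, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        """Normalized elliptical radius (1 on the boundary)."""
        return np.sqrt(((xx - self.cx) / self.rx) ** 2
                       + ((yy - self.cy) / self.ry) ** 2)


@dataclass(frozen=True)
class CellSpec:
    """Scene geometry for one cell: soma/nucleus ellipses and brightness."""

    soma: Ellipse
    nucleus: Ellipse
    intensity: float = 400.0

    def __post_init__(self) -> None:
        # nucleus boundary must lie strictly inside the soma ellipse
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        bx = self.nucleus.cx + self.nucleus.rx * np.cos(theta)
        by = self.nucleus.cy + self.nucleus.ry * np.sin(theta)
        if np.any(self.soma.radial(by, bx) >= 1.0):
            raise ValueError("nucleus must lie strictly inside the soma")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass(frozen=True)
class SceneParams:
    """Movie scene: geometry plus corruption model.

    ``noise_scale`` gives the per-channel photon-noise gain (variance =
    read_noise^2 + scale * intensity); ``bleach`` the per-channel linear
    intensity loss in fraction per minute; ``drift_px`` an (n_frames, 2)
    array of (dx, dy) stage displacements; ``artifact_prob`` the chance
    per frame of a transient defocus artifact.  ``seed`` fixes every
    stochastic draw.
    """

    shape: tuple[int, int] = (128, 128)
    cells: tuple[CellSpec, ...] = ()
    noise_scale: tuple[float, float] = (0.0, 0.0)  # (donor, acceptor)
    read_noise: float = 0.0
    bleach: tuple[float, float] = (0.0, 0.0)  # fraction/min (donor, acceptor)
    drift_px: np.ndarray | None = None
    artifact_prob: float = 0.0
    artifact_blur_px: float = 2.0
    artifact_gain: float = 1.15  # acceptor gain during a defocus artifact
    nucleus_dimming: float = 0.7
    edge_softness_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("scene needs at least one cell")
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must be a probability")
        if any(s < 0 for s in self.noise_scale) or self.read_noise < 0:
            raise ValueError("noise parameters must be non-negative")
        # reject overlapping somata so the ROI ground truth is unambiguous
        yy, xx = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        masks = [c.soma.radial(yy, xx) <= 1.0 for c in self.cells]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise ValueError(f"somata of cells {i} and {j} overlap")


@dataclass
class RenderTruth:
    """Everything injected into a rendered movie, for recovery tests."""

    shifts_px: np.ndarray  # (n_frames, 2) applied (dx, dy)
    rois: list[RoiMask]
    ratios: np.ndarray  # (n_cells, n_frames) ground-truth ratios
    artifact_frames: tuple[int, ...]
    bleach: tuple[float, float]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for one corruption type."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def render_movie(
    scene: SceneParams,
    ratio_traces: np.ndarray | Sequence[np.ndarray],
    timestamps_s: np.ndarray,
) -> tuple[TwoChannelStack, RenderTruth]:
    """Render a two-channel movie from per-cell ground-truth ratios.

    ``ratio_traces`` holds one ratio series per scene cell, sampled at
    ``timestamps_s``.  Acceptor = ratio x donor pixelwise within each
    cell, so with noise, drift and bleach disabled the extracted ROI
    ratio equals the ground truth exactly.  Identical inputs (including
    seed) render bit-identical stacks.
    """
    ratios = np.atleast_2d(np.asarray(ratio_traces, dtype=float))
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    n_cells, n_frames = ratios.shape
    if n_cells != len(scene.cells):
        raise ValueError("need exactly one ratio series per scene cell")
    if n_frames != len(timestamps_s):
        raise ValueError("ratio series and timestamps disagree in length")
    if scene.drift_px is not None and len(scene.drift_px) != n_frames:
        raise ValueError("drift path must have one (dx, dy) per frame")

    h, w = scene.shape
    yy, xx = np.mgrid[0:h, 0:w]
    t_min = timestamps_s / 60.0
    drift = (np.zeros((n_frames, 2)) if scene.drift_px is None
             else np.asarray(scene.drift_px, dtype=float))

    rng_noise_d = _substream(scene.seed, "noise_donor")
    rng_noise_a = _substream(scene.seed, "noise_acceptor")
    rng_art = _substream(scene.seed, "artifacts")

    artifact_frames = []
    donor = np.zeros((n_frames, h, w))
    acceptor = np.zeros((n_frames, h, w))
    k_soft = 2.0 / max(scene.edge_softness_px, 1e-6)

    for f in range(n_frames):
        dx, dy = drift[f]
        bl_d = max(0.0, 1.0 - scene.bleach[0] * t_min[f])
        bl_a = max(0.0, 1.0 - scene.bleach[1] * t_min[f])
        don = np.zeros((h, w))
        acc = np.zeros((h, w))
        for ci, cell in enumerate(scene.cells):
            soma = Ellipse(cell.soma.cx + dx, cell.soma.cy + dy,
                           cell.soma.rx, cell.soma.ry)
            nuc = Ellipse(cell.nucleus.cx + dx, cell.nucleus.cy + dy,
                          cell.nucleus.rx, cell.nucleus.ry)
            r_ax = min(soma.rx, soma.ry)
            prof = 1.0 / (1.0 + np.exp((soma.radial(yy, xx) - 1.0) * k_soft * r_ax))
            n_ax = min(nuc.rx, nuc.ry)
            nprof = 1.0 / (1.0 + np.exp((nuc.radial(yy, xx) - 1.0) * k_soft * n_ax))
            intensity = cell.intensity * prof * (1.0 - scene.nucleus_dimming * nprof)
            don += intensity
            acc += intensity * ratios[ci, f]
        don *= bl_d
        acc *= bl_a
        if scene.artifact_prob > 0 and rng_art.random() < scene.artifact_prob:
            artifact_frames.append(f)
            don = ndi.gaussian_filter(don, scene.artifact_blur_px)
            acc = ndi.gaussian_filter(acc, scene.artifact_blur_px) * scene.artifact_gain
        if scene.noise_scale[0] > 0 or scene.read_noise > 0:
            sd = np.sqrt(scene.read_noise**2 + scene.noise_scale[0] * don)
            don = don + sd * rng_noise_d.standard_normal((h, w))
        if scene.noise_scale[1] > 0 or scene.read_noise > 0:
            sa = np.sqrt(scene.read_noise**2 + scene.noise_scale[1] * acc)
            acc = acc + sa * rng_noise_a.standard_normal((h, w))
        donor[f] = np.clip(don, 0.0, None)
        acceptor[f] = np.clip(acc, 0.0, None)

    rois = []
    for ci, cell in enumerate(scene.cells):
        soma_mask = cell.soma.radial(yy, xx) <= 0.9
        nuc_mask = (cell.nucleus.radial(yy, xx) <= 1.2) & soma_mask
        rois.append(RoiMask(cell_id=f"cell-{ci + 1}", soma=soma_mask,
                            nucleus=nuc_mask))

    stack = TwoChannelStack(donor=donor, acceptor=acceptor,
                            timestamps_s=timestamps_s)
    truth = RenderTruth(
        shifts_px=drift, rois=rois, ratios=ratios,
        artifact_frames=tuple(artifact_frames), bleach=scene.bleach,
    )
    return stack, truth


def default_scene(
    n_cells: int,
    n_frames: int,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    **overrides,
) -> SceneParams:
    """Convenience layout: up to 8 non-overlapping cells on a grid, with
    mildly jittered geometry (seeded)."""
    rng = _substream(seed, "scene_layout")
    h, w = shape
    cols = int(np.ceil(np.sqrt(n_cells)))
    rowsn = int(np.ceil(n_cells / cols))
    cells = []
    for i in range(n_cells):
        r, c = divmod(i, cols)
        cy = (r + 0.5) * h / rowsn + rng.uniform(-2, 2)
        cx = (c + 0.5) * w / cols + rng.uniform(-2, 2)
        rx = rng.uniform(9, 12)
        ry = rng.uniform(9, 12)
        nucleus = Ellipse(cx + rng.uniform(-1.5, 1.5), cy + rng.uniform(-1.5, 1.5),
                          rx * 0.4, ry * 0.4)
        cells.append(CellSpec(soma=Ellipse(cx, cy, rx, ry), nucleus=nucleus,
                              intensity=rng.uniform(300, 500)))
    params = dict(shape=shape, cells=tuple(cells), seed=seed)
    params.update(overrides)
    return SceneParams(**params)
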