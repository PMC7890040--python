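"""Synthetic pHluorin movies with exact ground truth.

The generator renders the phenomenology of a single-neuron pHluorin
recording on an astrocyte island: a faint neurite arbor over a brighter
soma, quenched stationary vesicle puncta (~3 px across, Gaussian sigma
~1 px) at a few percent of their dequenched brightness, stimulus-locked
fusion events with an instantaneous rise of 1.5-3 dF/F0 and exponential
decay, a global NH4Cl dequenching step that reveals the entire labeled
pool within two frames, a smooth multiplicative illumination field, and
mixed Poisson-Gaussian camera noise.

Defaults reproduce the reference acquisition paradigm: 2 Hz imaging,
30 s baseline (stimulation starts at frame 61), a 48-frame (24 s)
stimulation window, NH4Cl onset at frame 160, 200 frames total.  The
vesicle pool is scaled to 150 (real neurons carry thousands; desk-scale
movies keep every punctum resolvable on a 256 x 256 field).

Every random draw derives from ``SimulationScenario.seed``; the same
scenario renders bit-identical movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .detect import AcquisitionParadigm
from .movie_io import TimeLapse

__all__ = [
    "SimulationScenario",
    "GroundTruthEvent",
    "GroundTruth",
    "simulate_movie",
    "default_scenarios",
]


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of one synthetic recording."""

    shape: tuple[int, int] = (256, 256)
    n_frames: int = 200
    frame_rate_hz: float = 2.0
    baseline_frames: int = 30
    stim_start_frame: int = 61  # 30 s baseline at 2 Hz
    stim_len_frames: int = 48  # 16 trains x 1.5 s = 24 s
    nh4_start_frame: int = 160
    post_stim_tail_frames: int = 0

    n_vesicles: int = 150
    n_events: int = 60
    event_amplitude_range: tuple[float, float] = (1.5, 3.0)  # dF/F0
    event_amplitude_counts: float | None = None  # absolute override
    event_decay_tau_s: float = 2.0
    punctum_sigma_px: float = 1.0
    dequench_amplitude: float = 600.0  # counts per single vesicle at NH4
    amplitude_jitter: float = 0.1  # relative vesicle-brightness spread
    quenched_fraction: float = 0.05  # resting brightness vs dequenched
    nonacidic_fraction: float = 0.0  # vesicles already bright pre-NH4

    n_synapses: int = 40
    synapse_radius_px: float = 2.5  # ~1 um bouton at 0.2 um/px
    synaptic_event_fraction: float = 0.5
    cluster_fraction: float = 0.0  # fraction of vesicles inside clusters
    cluster_size: int = 3

    background_level: float = 80.0
    neurite_level: float = 220.0
    soma_level: float = 500.0
    soma_nh4_response: float = 350.0  # diffuse somatic dequenching step
    soma_radius_px: int = 12
    n_neurites: int = 6

    illumination_gradient_strength: float = 0.2
    gaussian_noise_sd: float = 4.0
    poisson_noise: bool = True
    vesicle_mobility_px: float = 0.0  # random-walk SD per frame, off
    saturate_patch: bool = False
    bit_depth: int | None = 16

    min_event_separation_px: float = 6.0
    min_vesicle_separation_px: float = 4.0
    synapse_separation_px: float = 9.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events > self.n_vesicles:
            raise ValueError("n_events must be <= n_vesicles")
        if self.event_amplitude_range[0] <= 0:
            raise ValueError("event amplitudes must be positive")
        last_event = self.stim_start_frame + self.stim_len_frames + self.post_stim_tail_frames
        if last_event > self.nh4_start_frame:
            raise ValueError("event window must end before NH4 onset")
        if self.nh4_start_frame > self.n_frames:
            raise ValueError("nh4_start_frame beyond the movie length")

    @property
    def paradigm(self) -> AcquisitionParadigm:
        return AcquisitionParadigm(
            frame_rate_hz=self.frame_rate_hz,
            baseline_frames=self.baseline_frames,
            stim_start_frame=self.stim_start_frame,
            stim_len_frames=self.stim_len_frames,
            nh4_start_frame=self.nh4_start_frame,
        )


@dataclass(frozen=True)
class GroundTruthEvent:
    row: float
    col: float
    start_frame: int  # 1-based
    amplitude_dff: float
    amplitude_counts: float
    tau_s: float
    synaptic: bool


@dataclass(frozen=True)
class GroundTruth:
    """Everything the renderer knows; consistent with the movie by
    construction."""

    vesicle_positions: np.ndarray  # (N, 2) float, one row per vesicle
    events: tuple[GroundTruthEvent, ...]
    synapse_centers: np.ndarray  # (M, 2)
    synapse_mask: np.ndarray  # boolean, synapse disks
    neurite_mask: np.ndarray = field(repr=False, default=None)
    illumination: np.ndarray = field(repr=False, default=None)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "row": e.row,
                    "col": e.col,
                    "start_frame": e.start_frame,
                    "amplitude_dff": e.amplitude_dff,
                    "amplitude_counts": e.amplitude_counts,
                    "tau_s": e.tau_s,
                    "synaptic": e.synaptic,
                }
                for e in self.events
            ],
            columns=["row", "col", "start_frame", "amplitude_dff", "amplitude_counts", "tau_s", "synaptic"],
        )

    def vesicles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vesicle_positions, columns=["row", "col"])


def _grow_neurites(rng: np.random.Generator, shape, soma, n_neurites: int) -> np.ndarray:
    """Neurite arbor as dilated random smooth curves from the soma."""
    mask = np.zeros(shape, dtype=bool)
    n_steps = int(2.2 * max(shape))
    for _ in range(n_neurites):
        angle = rng.uniform(0, 2 * np.pi)
        r, c = float(soma[0]), float(soma[1])
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.15)
            r += np.sin(angle)
            c += np.cos(angle)
            if not (1 <= r < shape[0] - 1):
                r = np.clip(r, 1, shape[0] - 2)
                angle = -angle
            if not (1 <= c < shape[1] - 1):
                c = np.clip(c, 1, shape[1] - 2)
                angle = np.pi - angle
            mask[int(round(r)), int(round(c))] = True
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def _greedy_pick(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n: int,
    min_sep: float,
    keepout: list[tuple[np.ndarray, float]] | None = None,
    what: str = "sites",
) -> np.ndarray:
    """Pick n candidate points with pairwise distance >= min_sep,
    avoiding keep-out neighbourhoods; deterministic for a given rng."""
    order = rng.permutation(len(candidates))
    chosen: list[np.ndarray] = []
    for idx in order:
        p = candidates[idx].astype(float)
        if chosen and np.min(np.linalg.norm(np.asarray(chosen) - p, axis=1)) < min_sep:
            continue
        blocked = False
        for pts, radius in keepout or []:
            if len(pts) and np.min(np.linalg.norm(np.asarray(pts, float) - p, axis=1)) < radius:
                blocked = True
                break
        if blocked:
            continue
        chosen.append(p)
        if len(chosen) == n:
            return np.asarray(chosen)
    raise ValueError(f"could not place {n} {what} with separation {min_sep}")


def _stamp_gaussian(image: np.ndarray, row: float, col: float, amplitude: float, sigma: float) -> None:
    """Add a 2-D Gaussian punctum (peak = amplitude) in place."""
    radius = int(np.ceil(4 * sigma))
    r0, r1 = int(np.floor(row)) - radius, int(np.floor(row)) + radius + 1
    c0, c1 = int(np.floor(col)) - radius, int(np.floor(col)) + radius + 1
    r0c, r1c = max(r0, 0), min(r1, image.shape[0])
    c0c, c1c = max(c0, 0), min(c1, image.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None] - row
    cc = np.arange(c0c, c1c)[None, :] - col
    image[r0c:r1c, c0c:c1c] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _paint_disks(shape, centers: np.ndarray, radius: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, c in np.asarray(centers, float).reshape(-1, 2):
        r0, r1 = int(np.floor(r - radius)), int(np.ceil(r + radius)) + 1
        c0, c1 = int(np.floor(c - radius)), int(np.ceil(c + radius)) + 1
        r0, r1 = max(r0, 0), min(r1, shape[0])
        c0, c1 = max(c0, 0), min(c1, shape[1])
        rr = np.arange(r0, r1)[:, None] - r
        cc = np.arange(c0, c1)[None, :] - c
        mask[r0:r1, c0:c1] |= (rr**2 + cc**2) <= radius**2
    return mask


def simulate_movie(
    scenario: SimulationScenario,
) -> tuple[TimeLapse, GroundTruth, np.ndarray]:
    """Render one synthetic recording.

    Returns the movie, its ground truth, and the synapse-marker image
    (dark synapse puncta on a bright background, the contrast convention
    the mask pipeline expects).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    shape = tuple(sc.shape)

    # --- static scene ----------------------------------------------------
    soma = (
        int(rng.integers(shape[0] // 3, 2 * shape[0] // 3)),
        int(rng.integers(shape[1] // 3, 2 * shape[1] // 3)),
    )
    neurites = _grow_neurites(rng, shape, soma, sc.n_neurites)
    soma_disk = _paint_disks(shape, np.array([soma], float), sc.soma_radius_px)
    base = (
        sc.background_level
        + sc.neurite_level * ndimage.gaussian_filter(neurites.astype(float), 1.0)
        + sc.soma_level * ndimage.gaussian_filter(soma_disk.astype(float), 2.0)
    )

    # candidate vesicle/synapse sites: on neurites, away from soma/border
    rows, cols = np.nonzero(neurites)
    dist_soma = np.hypot(rows - soma[0], cols - soma[1])
    margin = 4
    ok = (
        (dist_soma > sc.soma_radius_px + 10)
        & (rows >= margin) & (rows < shape[0] - margin)
        & (cols >= margin) & (cols < shape[1] - margin)
    )
    candidates = np.stack([rows[ok], cols[ok]], axis=1)

    synapse_centers = _greedy_pick(
        rng, candidates, sc.n_synapses, sc.synapse_separation_px, what="synapses"
    )
    synapse_mask = _paint_disks(shape, synapse_centers, sc.synapse_radius_px)

    # --- event and vesicle placement ------------------------------------
    n_syn_events = int(round(sc.synaptic_event_fraction * sc.n_events))
    if n_syn_events > sc.n_synapses:
        raise ValueError("more synaptic events requested than synapses")
    syn_sites = synapse_centers[: n_syn_events]
    extra_sites = _greedy_pick(
        rng, candidates, sc.n_events - n_syn_events, sc.min_event_separation_px,
        keepout=[(synapse_centers, 5.0), (syn_sites, sc.min_event_separation_px)],
        what="extra-synaptic events",
    ) if sc.n_events - n_syn_events else np.empty((0, 2))
    event_sites = np.concatenate([syn_sites, extra_sites]) if len(syn_sites) or len(extra_sites) else np.empty((0, 2))
    event_synaptic = np.array([True] * n_syn_events + [False] * (sc.n_events - n_syn_events))

    n_clustered = int(sc.cluster_fraction * sc.n_vesicles) // sc.cluster_size * sc.cluster_size
    n_clusters = n_clustered // sc.cluster_size
    n_singles = sc.n_vesicles - sc.n_events - n_clustered
    if n_singles < 0:
        raise ValueError("n_vesicles too small for the requested events and clusters")
    rest_sites = _greedy_pick(
        rng, candidates, n_singles + n_clusters, sc.min_vesicle_separation_px,
        keepout=[(event_sites, sc.min_vesicle_separation_px)] if len(event_sites) else None,
        what="vesicles",
    ) if n_singles + n_clusters else np.empty((0, 2))
    single_sites = rest_sites[:n_singles]
    cluster_sites = rest_sites[n_singles:]

    vesicles = [event_sites, single_sites]
    for site in cluster_sites:
        jitter = rng.uniform(-0.5, 0.5, size=(sc.cluster_size, 2))
        vesicles.append(site[None, :] + jitter)
    nonempty = [np.asarray(v, float).reshape(-1, 2) for v in vesicles if len(v)]
    vesicle_positions = np.concatenate(nonempty) if nonempty else np.empty((0, 2))

    n_ves = len(vesicle_positions)
    amplitudes = sc.dequench_amplitude * (
        1.0 + rng.uniform(-sc.amplitude_jitter, sc.amplitude_jitter, size=n_ves)
    )
    quench = np.full(n_ves, sc.quenched_fraction)
    if sc.nonacidic_fraction > 0 and n_ves > sc.n_events:
        # only resting (non-event) vesicles can be pre-dequenched
        n_bright = int(round(sc.nonacidic_fraction * n_ves))
        idx = sc.n_events + rng.permutation(n_ves - sc.n_events)[:n_bright]
        quench[idx] = 1.0

    full_img = np.zeros(shape)
    quenched_img = np.zeros(shape)
    for (r, c), amp, q in zip(vesicle_positions, amplitudes, quench):
        _stamp_gaussian(full_img, r, c, amp, sc.punctum_sigma_px)
        _stamp_gaussian(quenched_img, r, c, q * amp, sc.punctum_sigma_px)
    dequench_img = full_img - quenched_img
    # acidic compartments in the soma (TGN, transiting vesicles) dequench
    # too, as a diffuse unresolvable response
    dequench_img = dequench_img + sc.soma_nh4_response * ndimage.gaussian_filter(
        soma_disk.astype(float), 2.0
    )
    static = base + quenched_img

    # --- events ----------------------------------------------------------
    event_window = sc.stim_len_frames + sc.post_stim_tail_frames
    starts = rng.integers(sc.stim_start_frame, sc.stim_start_frame + event_window, size=sc.n_events)
    dffs = rng.uniform(*sc.event_amplitude_range, size=sc.n_events)
    tau_frames = sc.event_decay_tau_s * sc.frame_rate_hz
    events: list[GroundTruthEvent] = []
    event_patches: list[tuple[int, np.ndarray, tuple[slice, slice]]] = []
    # programmed dF/F0 is what a 3x3 ROI measurement reports (the
    # convention of the reference traces), so the peak-pixel amplitude
    # is scaled by the inverse ROI-mean fraction of the punctum profile
    edge = np.exp(-0.5 / sc.punctum_sigma_px**2)
    roi_mean_frac = (1.0 + 2.0 * edge) ** 2 / 9.0
    for k in range(sc.n_events):
        r, c = event_sites[k]
        rr, cc = int(round(r)), int(round(c))
        local = static[max(rr - 1, 0) : rr + 2, max(cc - 1, 0) : cc + 2].mean()
        if sc.event_amplitude_counts is not None:
            # fixed absolute brightness (e.g. matched to the vesicle unit)
            amp_counts = sc.event_amplitude_counts
            dffs[k] = amp_counts * roi_mean_frac / local
        else:
            amp_counts = dffs[k] * local / roi_mean_frac
        events.append(
            GroundTruthEvent(
                row=float(r), col=float(c), start_frame=int(starts[k]),
                amplitude_dff=float(dffs[k]), amplitude_counts=float(amp_counts),
                tau_s=sc.event_decay_tau_s, synaptic=bool(event_synaptic[k]),
            )
        )
        patch = np.zeros(shape)
        _stamp_gaussian(patch, r, c, 1.0, sc.punctum_sigma_px)
        sl = ndimage.find_objects((patch > 1e-6).astype(np.int8))[0]
        event_patches.append((int(starts[k]) - 1, amp_counts * patch[sl], sl))

    # --- illumination and rendering --------------------------------------
    if sc.illumination_gradient_strength > 0:
        rough = rng.normal(size=shape)
        smooth = ndimage.gaussian_filter(rough, sigma=max(shape) / 6, mode="reflect")
        smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min()) - 0.5
        illumination = 1.0 + sc.illumination_gradient_strength * smooth
    else:
        illumination = np.ones(shape)

    nh4_0 = sc.nh4_start_frame - 1
    movie = np.empty((sc.n_frames,) + shape, dtype=np.float64)
    for t in range(sc.n_frames):
        frame = static.copy()
        if t >= nh4_0:  # dequenching completes within 2 frames
            frame += dequench_img * (0.5 if t == nh4_0 else 1.0)
        for t0, patch, sl in event_patches:
            if t0 <= t < nh4_0:
                decay = np.exp(-(t - t0) / tau_frames)
                if decay > 1e-3:
                    frame[sl] += patch * decay
        movie[t] = frame * illumination

    if sc.poisson_noise:
        movie = rng.poisson(movie).astype(np.float64)
    if sc.gaussian_noise_sd > 0:
        movie += rng.normal(0.0, sc.gaussian_noise_sd, size=movie.shape)
    np.clip(movie, 0, None, out=movie)

    if sc.bit_depth is not None:
        limit = 2**sc.bit_depth - 1
        dtype = np.uint8 if sc.bit_depth <= 8 else np.uint16
        movie = np.clip(np.rint(movie), 0, limit).astype(dtype)

    if sc.saturate_patch:
        if sc.bit_depth is None:
            raise ValueError("saturate_patch requires an integer bit depth")
        limit = 2**sc.bit_depth - 1
        pr, pc = shape[0] - 12, shape[1] - 12  # far corner, outside the soma
        movie[nh4_0:, pr : pr + 5, pc : pc + 5] = limit

    # --- synapse marker image (dark puncta on bright background) --------
    # synapses rendered as slightly blurred disks matching the ground-
    # truth footprint, so the mask pipeline has a well-defined target
    marker = 200.0 - 150.0 * ndimage.gaussian_filter(synapse_mask.astype(float), 0.4)
    marker += rng.normal(0.0, 1.5, size=shape)
    np.clip(marker, 0, None, out=marker)

    timelapse = TimeLapse(frames=movie, frame_rate_hz=sc.frame_rate_hz)
    truth = GroundTruth(
        vesicle_positions=vesicle_positions,
        events=tuple(events),
        synapse_centers=synapse_centers,
        synapse_mask=synapse_mask,
        neurite_mask=neurites,
        illumination=illumination,
    )
    return timelapse, truth, marker


def default_scenarios(seed: int = 0) -> dict[str, SimulationScenario]:
    """Named fixture scenarios used across the test suite.

    clean
        The default study conditions (60 events of 1.5-3 dF/F0 among
        150 vesicles).
    noisy
        Same scene with triple the Gaussian read noise.
    null
        No fusion events (false-positive control).
    pool
        150 identical, well-separated vesicles with event brightness
        matched to the single-vesicle unit (pool-recovery control).
    clustered_pool
        As ``pool`` but a third of the vesicles sit in 3-vesicle
        clusters (tests the corrected estimates).
    saturated
        Clean scene plus a saturated patch outside the soma during NH4
        superfusion (QC control).
    """
    base = SimulationScenario(seed=seed)
    pool = replace(
        base,
        n_events=12,
        n_vesicles=150,
        event_amplitude_counts=600.0,  # matched to the vesicle unit
        amplitude_jitter=0.0,
        illumination_gradient_strength=0.0,
        min_vesicle_separation_px=8.0,
        min_event_separation_px=8.0,
        synaptic_event_fraction=0.0,
    )
    return {
        "clean": base,
        "noisy": replace(base, gaussian_noise_sd=12.0),
        "null": replace(base, n_events=0, synaptic_event_fraction=0.0),
        "pool": pool,
        "clustered_pool": replace(pool, cluster_fraction=1 / 3, cluster_size=3),
        "saturated": replace(base, saturate_patch=True),
    }
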