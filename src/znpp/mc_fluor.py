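"""Layered Monte Carlo photon transport with fluorescence (desk scale).

MCML-style transport through a stack of plane-parallel tissue layers:
dimensionless step sampling with partial steps at layer boundaries,
Henyey-Greenstein scattering, Fresnel reflection at the external surfaces and
survival roulette.  Photons are launched across the face of an optical fibre
in contact with the surface, with a cosine-distributed launch angle truncated
at the fibre's numerical aperture (refracted into tissue); the fibre is
embedded in a perfectly reflecting ferrule.  A photon is detected when it
exits within the fibre face inside the acceptance cone
(sin(theta_tissue) <= NA / n_tissue; the fibre face is treated as
index-matched to the tissue).

Fluorescence uses weighted direct emission: every absorption deposition
contributes fluorescence weight (deposited x fluorophore_fraction x
quantum_yield) emitted isotropically at the deposition site and transported
with the emission-wavelength optical properties.  A spawn-control step
(probability proportional to the contribution weight) keeps the number of
emission photons tractable without bias.

Energy accounting: survival roulette conserves weight only in expectation,
so every ledger carries a signed ``roulette_net`` entry (weight removed by
kills minus weight added by survival boosts); with it, every run's ledger
sums to the injected weight to floating-point precision.

The random stream is counter-based: each photon's generator is keyed by
(seed, photon index), so results are bit-reproducible and independent of
execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .references import VesselGeometry, corrected_mu_a

__all__ = [
    "TissueLayer",
    "TissueModel",
    "FiberProbe",
    "McResult",
    "run_excitation",
    "run_fluorescence",
    "transport_emission",
    "simulated_blood_index",
    "sweep",
    "default_tissue_model",
    "EMISSION_WAVELENGTHS_NM",
]

#: Fixed emission wavelengths of the simulation design: 561 and 576 nm carry
#: tissue autofluorescence only; 593 nm carries autofluorescence plus ZnPP
#: (generated only in the blood-perfused stroma).
EMISSION_WAVELENGTHS_NM = (561.0, 576.0, 593.0)

_W_THRESH = 1e-4
_P_SURV = 0.1

LEDGER_KEYS = ("detected", "escaped_top", "transmitted_bottom", "absorbed", "roulette_net")


@dataclass(frozen=True)
class TissueLayer:
    """One plane-parallel layer with excitation and emission optical properties.

    Coefficients in mm^-1; ``fluorophore_fraction`` is the contribution of
    fluorophores to the absorption coefficient, ``quantum_yield`` the
    fluorescence quantum efficiency.
    """

    thickness_mm: float
    mu_a_exc: float
    mu_s_exc: float
    g_exc: float
    mu_a_em: float
    mu_s_em: float
    g_em: float
    fluorophore_fraction: float = 0.1
    quantum_yield: float = 1.0

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")
        for name in ("mu_a_exc", "mu_s_exc", "mu_a_em", "mu_s_em"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("g_exc", "g_em"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (-1, 1)")
        if not 0 <= self.fluorophore_fraction <= 1:
            raise ValueError("fluorophore_fraction must be in [0, 1]")
        if not 0 <= self.quantum_yield <= 1:
            raise ValueError("quantum_yield must be in [0, 1]")


@dataclass(frozen=True)
class TissueModel:
    layers: tuple[TissueLayer, ...]
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("tissue model needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def z_edges(self) -> np.ndarray:
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness_mm for l in self.layers])]
        )


@dataclass(frozen=True)
class FiberProbe:
    diameter_um: float = 1000.0
    numerical_aperture: float = 0.22
    refractive_index: float = 1.46
    ferrule_diameter_mm: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("NA must be in (0, 1)")
        if self.diameter_um <= 0:
            raise ValueError("fibre diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_um * 1e-3 / 2.0


@dataclass
class McResult:
    """Per-run weight ledgers, normalised to the injected excitation weight."""

    n_photons: int
    seed: int
    ledger: dict[str, float]
    detected_excitation: float
    absorbed_depth_profile: tuple[np.ndarray, np.ndarray] | None = None
    #: (emission key, origin layer index) -> detected weight per injected photon
    detected_fluorescence: dict = field(default_factory=dict)
    #: emission key -> ledger normalised to the spawned emission weight
    fluorescence_ledgers: dict = field(default_factory=dict)
    #: emission key -> spawned emission weight per injected photon
    spawned_weight: dict = field(default_factory=dict)

    def ledger_defect(self) -> float:
        """Relative departure of the ledger sum from unity."""
        return abs(sum(self.ledger.values()) - 1.0)

    def total_detected_fluorescence(self, key) -> float:
        return sum(
            v for (k, _layer), v in self.detected_fluorescence.items() if k == key
        )


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

_U64_GOLD = np.uint64(0x9E3779B97F4A7C15)
_U64_MULT = np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _seed_state(seed, idx):
    x = (np.uint64(seed) ^ (np.uint64(idx) * _U64_GOLD)) + _U64_GOLD
    # splitmix64 finaliser
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    x = x ^ (x >> np.uint64(31))
    if x == np.uint64(0):
        x = _U64_GOLD
    return x


@njit(cache=True, inline="always")
def _rng(state):
    # xorshift64*; returns (new_state, uniform in [0, 1))
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    r = state * _U64_MULT
    return state, (r >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _fresnel_reflectance(cos_i, n_rel):
    # n_rel = n_inside / n_outside; unpolarised
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport(
    n_photons,
    seed,
    seed_offset,
    mu_a,
    mu_s,
    g,
    z_edges,
    n_rel,
    fiber_r,
    ferrule_r,
    sin_acc,
    sin_launch,
    start_mode,
    sx,
    sy,
    sz,
    slayer,
    sweight,
    ff,
    qy,
    w_ref,
    do_spawn,
    spawn_x,
    spawn_y,
    spawn_z,
    spawn_layer,
    spawn_w,
    nz_bins,
    z_hist_max,
):
    n_layers = mu_a.shape[0]
    ledger = np.zeros(5)
    detected_by_layer = np.zeros(n_layers)
    abs_hist = np.zeros(nz_bins)
    n_spawn = 0
    spawn_cap = spawn_x.shape[0]
    spawn_overflow = 0.0  # weight that could not be buffered

    for i in range(n_photons):
        state = _seed_state(seed, i + seed_offset)
        if start_mode == 0:
            state, u1 = _rng(state)
            state, u2 = _rng(state)
            rr = fiber_r * math.sqrt(u1)
            phi = 2.0 * math.pi * u2
            x = rr * math.cos(phi)
            y = rr * math.sin(phi)
            z = 0.0
            state, u3 = _rng(state)
            state, u4 = _rng(state)
            sin2 = sin_launch * sin_launch * u3  # cosine-weighted within cone
            sint = math.sqrt(sin2)
            cost = math.sqrt(1.0 - sin2)
            psi = 2.0 * math.pi * u4
            dx = sint * math.cos(psi)
            dy = sint * math.sin(psi)
            dz = cost
            w = 1.0
            layer = 0
            origin = 0
        else:
            x = sx[i]
            y = sy[i]
            z = sz[i]
            layer = slayer[i]
            origin = layer
            w = sweight[i]
            state, u1 = _rng(state)
            state, u2 = _rng(state)
            dz = 2.0 * u1 - 1.0
            sint = math.sqrt(max(0.0, 1.0 - dz * dz))
            psi = 2.0 * math.pi * u2
            dx = sint * math.cos(psi)
            dy = sint * math.sin(psi)

        alive = True
        n_tir = 0  # consecutive total internal reflections without interaction
        while alive:
            mt = mu_a[layer] + mu_s[layer]
            state, u = _rng(state)
            s_dimless = -math.log(max(u, 1e-300))

            interact = False
            while True:
                # guard against photons trapped by repeated total internal
                # reflection in non-interacting layers (artifact of the
                # infinite-plane idealisation); tallied as escaped
                if n_tir > 200:
                    ledger[1] += w
                    alive = False
                    break
                if dz > 0.0:
                    db = (z_edges[layer + 1] - z) / dz
                elif dz < 0.0:
                    db = (z_edges[layer] - z) / dz
                else:
                    db = 1e30
                if db < 0.0:
                    db = 0.0
                if mt * db <= s_dimless:
                    if db >= 1e30:
                        # travelling parallel in a non-interacting layer
                        ledger[1] += w
                        alive = False
                        break
                    x += dx * db
                    y += dy * db
                    s_dimless -= mt * db
                    if dz < 0.0:
                        z = z_edges[layer]
                        if layer == 0:
                            # top surface
                            cos_i = -dz
                            r_exit = math.sqrt(x * x + y * y)
                            sin_exit = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                            if r_exit <= fiber_r and sin_exit <= sin_acc:
                                ledger[0] += w
                                detected_by_layer[origin] += w
                                alive = False
                                break
                            elif r_exit <= ferrule_r:
                                dz = -dz  # perfectly reflecting ferrule
                            else:
                                refl = _fresnel_reflectance(cos_i, n_rel)
                                state, u = _rng(state)
                                if u < refl:
                                    dz = -dz
                                    if refl >= 1.0:
                                        n_tir += 1
                                else:
                                    ledger[1] += w
                                    alive = False
                                    break
                        else:
                            layer -= 1
                            mt = mu_a[layer] + mu_s[layer]
                    else:
                        z = z_edges[layer + 1]
                        if layer == n_layers - 1:
                            cos_i = dz
                            refl = _fresnel_reflectance(cos_i, n_rel)
                            state, u = _rng(state)
                            if u < refl:
                                dz = -dz
                                if refl >= 1.0:
                                    n_tir += 1
                            else:
                                ledger[2] += w
                                alive = False
                                break
                        else:
                            layer += 1
                            mt = mu_a[layer] + mu_s[layer]
                else:
                    step = s_dimless / mt
                    x += dx * step
                    y += dy * step
                    z += dz * step
                    interact = True
                    break

            if not alive:
                break

            if interact and mt > 0.0:
                n_tir = 0
                dw = w * mu_a[layer] / mt
                if dw > 0.0:
                    w -= dw
                    ledger[3] += dw
                    if nz_bins > 0:
                        bz = int(z / z_hist_max * nz_bins)
                        if bz >= nz_bins:
                            bz = nz_bins - 1
                        abs_hist[bz] += dw
                    if do_spawn == 1 and ff[layer] > 0.0:
                        contrib = dw * ff[layer] * qy
                        if contrib >= w_ref:
                            p_spawn = 1.0
                            w_new = contrib
                        else:
                            p_spawn = contrib / w_ref
                            w_new = w_ref
                        state, u = _rng(state)
                        if u < p_spawn:
                            if n_spawn < spawn_cap:
                                spawn_x[n_spawn] = x
                                spawn_y[n_spawn] = y
                                spawn_z[n_spawn] = z
                                spawn_layer[n_spawn] = layer
                                spawn_w[n_spawn] = w_new
                                n_spawn += 1
                            else:
                                spawn_overflow += w_new

                # Henyey-Greenstein scattering
                gl = g[layer]
                state, u = _rng(state)
                if abs(gl) < 1e-8:
                    cost = 2.0 * u - 1.0
                else:
                    tmp = (1.0 - gl * gl) / (1.0 - gl + 2.0 * gl * u)
                    cost = (1.0 + gl * gl - tmp * tmp) / (2.0 * gl)
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                sint = math.sqrt(1.0 - cost * cost)
                state, u = _rng(state)
                psi = 2.0 * math.pi * u
                cosp = math.cos(psi)
                sinp = math.sin(psi)
                if abs(dz) > 0.99999:
                    dx = sint * cosp
                    dy = sint * sinp
                    dz = cost if dz > 0.0 else -cost
                else:
                    den = math.sqrt(1.0 - dz * dz)
                    dx_new = sint * (dx * dz * cosp - dy * sinp) / den + dx * cost
                    dy_new = sint * (dy * dz * cosp + dx * sinp) / den + dy * cost
                    dz_new = -sint * cosp * den + dz * cost
                    norm = math.sqrt(dx_new**2 + dy_new**2 + dz_new**2)
                    dx = dx_new / norm
                    dy = dy_new / norm
                    dz = dz_new / norm

            if w < _W_THRESH:
                state, u = _rng(state)
                if u < _P_SURV:
                    ledger[4] -= w * (1.0 / _P_SURV - 1.0)
                    w = w / _P_SURV
                else:
                    ledger[4] += w
                    alive = False

    return ledger, detected_by_layer, abs_hist, n_spawn, spawn_overflow


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------


def _layer_arrays(model: TissueModel, which: str):
    mu_a = np.array([getattr(l, f"mu_a_{which}") for l in model.layers])
    mu_s = np.array([getattr(l, f"mu_s_{which}") for l in model.layers])
    g = np.array([getattr(l, f"g_{which}") for l in model.layers])
    return mu_a, mu_s, g


_EMPTY_F = np.empty(0, dtype=np.float64)
_EMPTY_I = np.empty(0, dtype=np.int64)


def run_excitation(
    model: TissueModel,
    probe: FiberProbe,
    n_photons: int = 1_000_000,
    seed: int = 0,
    depth_bins: int = 200,
    _spawn: bool = False,
    _spawns_per_photon: float = 4.0,
) -> McResult | tuple[McResult, tuple]:
    """Transport excitation photons; returns the per-run weight ledger.

    The absorbed-weight depth profile is tallied into ``depth_bins`` bins
    over the full stack thickness.
    """
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1e3")
    z_edges = model.z_edges
    if z_edges[-1] <= 0:
        raise ValueError("layer stack has zero total thickness")
    mu_a, mu_s, g = _layer_arrays(model, "exc")
    # per-layer fluorescence conversion: fluorophore fraction x quantum yield
    ff = np.array(
        [l.fluorophore_fraction * l.quantum_yield for l in model.layers]
    )
    qy = 1.0
    sin_cone = probe.numerical_aperture / model.refractive_index

    if _spawn:
        ff_max = float(ff.max()) if ff.max() > 0 else 1.0
        w_ref = ff_max / _spawns_per_photon
        cap = int(n_photons * _spawns_per_photon * 3) + 1000
        spawn_x = np.empty(cap)
        spawn_y = np.empty(cap)
        spawn_z = np.empty(cap)
        spawn_layer = np.empty(cap, dtype=np.int64)
        spawn_w = np.empty(cap)
        do_spawn = 1
    else:
        w_ref = 1.0
        spawn_x = spawn_y = spawn_z = spawn_w = _EMPTY_F
        spawn_layer = _EMPTY_I
        do_spawn = 0

    ledger, _, abs_hist, n_spawn, overflow = _transport(
        int(n_photons),
        int(seed),
        0,
        mu_a,
        mu_s,
        g,
        z_edges,
        model.refractive_index,  # n_tissue / n_air
        probe.radius_mm,
        probe.ferrule_diameter_mm / 2.0,
        sin_cone,
        sin_cone,
        0,
        _EMPTY_F,
        _EMPTY_F,
        _EMPTY_F,
        _EMPTY_I,
        _EMPTY_F,
        ff,
        qy,
        w_ref,
        do_spawn,
        spawn_x,
        spawn_y,
        spawn_z,
        spawn_layer,
        spawn_w,
        int(depth_bins),
        float(z_edges[-1]),
    )
    if _spawn and overflow > 0:
        raise RuntimeError(
            "fluorescence spawn buffer overflow; reduce _spawns_per_photon"
        )
    n = float(n_photons)
    result = McResult(
        n_photons=int(n_photons),
        seed=int(seed),
        ledger={k: v / n for k, v in zip(LEDGER_KEYS, ledger)},
        detected_excitation=ledger[0] / n,
        absorbed_depth_profile=(
            (np.arange(depth_bins) + 0.5) * z_edges[-1] / depth_bins,
            abs_hist / n,
        ),
    )
    if _spawn:
        spawns = (
            spawn_x[:n_spawn].copy(),
            spawn_y[:n_spawn].copy(),
            spawn_z[:n_spawn].copy(),
            spawn_layer[:n_spawn].copy(),
            spawn_w[:n_spawn].copy(),
        )
        return result, spawns
    return result


def transport_emission(
    model: TissueModel,
    probe: FiberProbe,
    positions: np.ndarray,
    layers: np.ndarray,
    weights: np.ndarray,
    seed: int = 0,
    which: str = "em",
    mu_override: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    seed_offset: int = 0,
) -> tuple[dict[str, float], np.ndarray]:
    """Transport isotropically emitted photons from given start points.

    Returns (ledger normalised to the total start weight, detected weight by
    origin layer, unnormalised).  Exposed separately so emission transport
    can be validated against closed-form detection geometry.
    """
    positions = np.asarray(positions, dtype=float)
    if mu_override is not None:
        mu_a, mu_s, g = mu_override
    else:
        mu_a, mu_s, g = _layer_arrays(model, which)
    sin_cone = probe.numerical_aperture / model.refractive_index
    n = positions.shape[0]
    ledger, det_by_layer, _, _, _ = _transport(
        int(n),
        int(seed),
        int(seed_offset),
        mu_a,
        mu_s,
        g,
        model.z_edges,
        model.refractive_index,
        probe.radius_mm,
        probe.ferrule_diameter_mm / 2.0,
        sin_cone,
        sin_cone,
        1,
        np.ascontiguousarray(positions[:, 0]),
        np.ascontiguousarray(positions[:, 1]),
        np.ascontiguousarray(positions[:, 2]),
        np.ascontiguousarray(layers, dtype=np.int64),
        np.ascontiguousarray(weights, dtype=float),
        np.zeros(len(model.layers)),
        0.0,
        1.0,
        0,
        _EMPTY_F,
        _EMPTY_F,
        _EMPTY_F,
        _EMPTY_I,
        _EMPTY_F,
        0,
        1.0,
    )
    total = float(np.sum(weights))
    norm = total if total > 0 else 1.0
    return {k: v / norm for k, v in zip(LEDGER_KEYS, ledger)}, det_by_layer


def run_fluorescence(
    model: TissueModel,
    probe: FiberProbe,
    emission_properties: Mapping[float, Sequence[tuple[float, float, float]]] | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    spawns_per_photon: float = 4.0,
) -> McResult:
    """Excitation transport plus weighted-direct-emission fluorescence.

    ``emission_properties`` maps an emission key (e.g. wavelength in nm) to
    per-layer (mu_a_em, mu_s_em, g_em) triples; when omitted, the model's own
    emission properties are used under the key ``"em"``.  One excitation pass
    generates the emission sources; each emission key re-transports them with
    its own optical properties (fluorophore spatial distribution is set by
    the layers' ``fluorophore_fraction``).
    """
    exc_result, spawns = run_excitation(
        model,
        probe,
        n_photons=n_photons,
        seed=seed,
        _spawn=True,
        _spawns_per_photon=spawns_per_photon,
    )
    sx, sy, sz, slayer, sw = spawns
    positions = np.column_stack([sx, sy, sz])
    if emission_properties is None:
        emission_properties = {"em": [
            (l.mu_a_em, l.mu_s_em, l.g_em) for l in model.layers
        ]}
    n_inj = float(n_photons)
    # common random numbers across emission keys: the keys differ only in
    # optical properties, so sharing the stream cancels most Monte Carlo
    # noise in between-wavelength ratios (e.g. the simulated blood index)
    for key, props in emission_properties.items():
        props = np.asarray(props, dtype=float)
        mu_override = (
            np.ascontiguousarray(props[:, 0]),
            np.ascontiguousarray(props[:, 1]),
            np.ascontiguousarray(props[:, 2]),
        )
        ledger, det_by_layer = transport_emission(
            model,
            probe,
            positions,
            slayer,
            sw,
            seed=seed,
            mu_override=mu_override,
            seed_offset=1_000_003,
        )
        exc_result.fluorescence_ledgers[key] = ledger
        exc_result.spawned_weight[key] = float(sw.sum()) / n_inj
        for li in range(len(model.layers)):
            exc_result.detected_fluorescence[(key, li)] = det_by_layer[li] / n_inj
    return exc_result


def simulated_blood_index(
    autofluorescence_561: float,
    autofluorescence_576: float,
    mu_561: float,
    mu_576: float,
) -> float:
    """Two-band blood absorption index from simulated autofluorescence.

    Both signals divided by exp(-a*mu) become equal when
    a = ln(G576/G561) / (mu561 - mu576); more blood gives a larger a.
    """
    if autofluorescence_561 <= 0 or autofluorescence_576 <= 0:
        raise ValueError("autofluorescence weights must be positive")
    return math.log(autofluorescence_576 / autofluorescence_561) / (mu_561 - mu_576)


def default_tissue_model(
    epithelium_um: float = 200.0,
    blood_fraction: float = 0.01,
    vessel_diameter_um: float = 24.0,
    mu_a_whole_exc: float = 197.21,
    mu_a_whole_em: float = 28.4,
    fluorophore_fraction: float = 0.1,
    quantum_yield: float = 1.0,
) -> TissueModel:
    """Three-layer lip mucosa model: epithelium (bloodless), 200-um
    superficial stroma and 10-mm lower stroma (blood-perfused, differing
    only by blood content from the superficial stroma).

    The stromal blood absorption is the vessel-packaged coefficient at the
    given blood fraction and vessel diameter; scattering is mucosa-scale
    (mu_s ~ 10-20 mm^-1, g = 0.9).
    """
    geom = VesselGeometry(vessel_diameter_um, blood_fraction)
    blood_exc = corrected_mu_a(mu_a_whole_exc, geom)
    blood_em = corrected_mu_a(mu_a_whole_em, geom)
    epithelium = TissueLayer(
        thickness_mm=epithelium_um * 1e-3,
        mu_a_exc=0.05, mu_s_exc=10.0, g_exc=0.9,
        mu_a_em=0.025, mu_s_em=9.0, g_em=0.9,
        fluorophore_fraction=fluorophore_fraction,
        quantum_yield=quantum_yield,
    )
    stroma_sup = TissueLayer(
        thickness_mm=0.2,
        mu_a_exc=0.05 + blood_exc, mu_s_exc=15.0, g_exc=0.9,
        mu_a_em=0.025 + blood_em, mu_s_em=13.0, g_em=0.9,
        fluorophore_fraction=fluorophore_fraction,
        quantum_yield=quantum_yield,
    )
    stroma_low = replace(stroma_sup, thickness_mm=10.0)
    return TissueModel(layers=(epithelium, stroma_sup, stroma_low))


def sweep(
    probe: FiberProbe | None = None,
    epithelium_um: Sequence[float] = (200.0,),
    vessel_diameter_um: Sequence[float] = (24.0,),
    blood_fraction: Sequence[float] = (0.01,),
    fiber_diameter_um: Sequence[float] = (1000.0,),
    n_photons: int = 20_000,
    seed: int = 0,
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Grid sweep over tissue geometry and probe diameter.

    Vessel diameter and blood fraction enter only through the packaged
    stromal absorption coefficient.  Each cell runs excitation + fluorescence
    with a seed derived as ``seed + cell_index`` (a 1-cell grid therefore
    equals a direct run at ``seed``).  Returns one row per cell with ledger
    and detected-fluorescence columns.
    """
    probe = probe or FiberProbe()
    model_kwargs = model_kwargs or {}
    rows = []
    cell = 0
    for ep in epithelium_um:
        for vd in vessel_diameter_um:
            for bf in blood_fraction:
                for fd in fiber_diameter_um:
                    model = default_tissue_model(
                        epithelium_um=ep,
                        blood_fraction=bf,
                        vessel_diameter_um=vd,
                        **model_kwargs,
                    )
                    cell_probe = replace(probe, diameter_um=fd)
                    res = run_fluorescence(
                        model,
                        cell_probe,
                        n_photons=n_photons,
                        seed=(seed + cell) % 2**31,
                    )
                    row = {
                        "epithelium_um": ep,
                        "vessel_diameter_um": vd,
                        "blood_fraction": bf,
                        "fiber_diameter_um": fd,
                        "seed": (seed + cell) % 2**31,
                        "n_photons": n_photons,
                        "detected_excitation": res.detected_excitation,
                        "detected_fluorescence": res.total_detected_fluorescence("em"),
                        "ledger_defect": res.ledger_defect(),
                    }
                    for k, v in res.ledger.items():
                        row[f"exc_{k}"] = v
                    rows.append(row)
                    cell += 1
    return pd.DataFrame(rows)
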