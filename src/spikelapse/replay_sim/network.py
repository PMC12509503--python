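"""Offline CA3-CA1 network: AELIF dynamics with conductance synapses.

The offline ("replay") state simulates all four populations (CA3/CA1
pyramidal cells and interneurons) with adaptive exponential
integrate-and-fire dynamics, bi-exponential conductance synapses, a
pooled dentate-gyrus Poisson drive onto CA3 pyramidal cells, and the
STDP-learned pyramidal weight matrices frozen as static synapses.
Integration is forward Euler at 0.1 ms with refractory clamping; the
extracellular proxy is the scaled sum of synaptic currents onto a random
subset of CA1 pyramidal cells,

    LFP(t) = 1 / (4 pi sigma r) * sum_i g_i(t) (V_i - E_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    CUE_DURATION_MS,
    CUE_RATE_HZ,
    CUE_WEIGHT_NS,
    CUE_WINDOW_CM,
    DG_DECAY_MS,
    DG_DELAY_MS,
    DG_P_CONNECT,
    DG_RATE_HZ,
    DG_RISE_MS,
    DG_WEIGHT_CUED_NS,
    DG_WEIGHT_SPONTANEOUS_NS,
    E_AMPA_MV,
    E_GABA_MV,
    INTERNEURON,
    OFFLINE_SYNAPSES,
    PYRAMIDAL,
    AelifParams,
    NetworkConfig,
    PlaceFieldMap,
)
from .stdp import random_connectivity

__all__ = ["OfflineNetwork", "SimResult", "build_offline_network", "simulate_offline"]

POP_ORDER = ("ca3_pyr", "ca3_int", "ca1_pyr", "ca1_int")


def _biexp_norm(tau_r: float, tau_d: float) -> float:
    """Scale so a unit-weight event gives a unit peak conductance."""
    tp = tau_d * tau_r / (tau_d - tau_r) * np.log(tau_d / tau_r)
    return 1.0 / (np.exp(-tp / tau_d) - np.exp(-tp / tau_r))


@dataclass
class _Channel:
    name: str
    tau_rise_ms: float
    tau_decay_ms: float
    E_mV: float
    delay_steps: int
    W: np.ndarray | None  # (N, N) in nS; None for external drives


class OfflineNetwork:
    """Static offline network ready for simulation."""

    def __init__(self, cfg: NetworkConfig, pfm_ca3: PlaceFieldMap,
                 pfm_ca1: PlaceFieldMap, channels: list[_Channel],
                 dg_mask: np.ndarray, params: dict[str, np.ndarray],
                 slices: dict[str, slice], lfp_cells: np.ndarray):
        self.cfg = cfg
        self.pfm_ca3 = pfm_ca3
        self.pfm_ca1 = pfm_ca1
        self.channels = channels
        self.dg_mask = dg_mask
        self.params = params
        self.slices = slices
        self.lfp_cells = lfp_cells
        self.n_total = len(params["C_m"])

    def population_of(self, ids: np.ndarray) -> np.ndarray:
        out = np.empty(len(ids), dtype=object)
        for name, sl in self.slices.items():
            out[(ids >= sl.start) & (ids < sl.stop)] = name
        return out


def _param_arrays(n_per_pop: dict[str, int]) -> tuple[dict[str, np.ndarray], dict[str, slice]]:
    fields = ["C_m", "g_L", "E_L", "theta", "Delta_T", "V_peak", "V_reset",
              "t_ref", "tau_w", "a", "b"]
    per_pop_params: dict[str, AelifParams] = {
        "ca3_pyr": PYRAMIDAL, "ca1_pyr": PYRAMIDAL,
        "ca3_int": INTERNEURON, "ca1_int": INTERNEURON,
    }
    slices: dict[str, slice] = {}
    arrays: dict[str, list] = {f: [] for f in fields}
    start = 0
    for pop in POP_ORDER:
        n = n_per_pop[pop]
        slices[pop] = slice(start, start + n)
        p = per_pop_params[pop]
        vals = [p.C_m_pF, p.g_L_nS, p.E_L_mV, p.theta_mV, p.Delta_T_mV,
                p.V_peak_mV, p.V_reset_mV, p.t_ref_ms, p.tau_w_ms, p.a_nS, p.b_pA]
        for f, v in zip(fields, vals):
            arrays[f].append(np.full(n, v))
        start += n
    return {f: np.concatenate(a) for f, a in arrays.items()}, slices


def build_offline_network(
    w33_norm: np.ndarray,
    w31_norm: np.ndarray,
    cfg: NetworkConfig,
    pfm_ca3: PlaceFieldMap,
    pfm_ca1: PlaceFieldMap,
    seed: int = 0,
    w_max_nS: float = 40.0,
) -> OfflineNetwork:
    """Assemble the offline network from learned pyramidal weights.

    ``w33_norm`` and ``w31_norm`` are the normalized STDP matrices for
    CA3->CA3 and CA3->CA1 (entries 0 where unconnected).  Fixed-weight
    connections are drawn per the offline synapse table; every per-synapse
    conductance (including the learned ones) is multiplied by the desk
    scale factor so mean input per neuron is size invariant.
    """
    rng = np.random.default_rng(seed)
    n_pyr, n_int = cfg.n_pyr, cfg.n_int
    if w33_norm.shape != (n_pyr, n_pyr) or w31_norm.shape != (n_pyr, n_pyr):
        raise ValueError("weight matrix shape does not match the population size")
    n_per_pop = {"ca3_pyr": n_pyr, "ca3_int": n_int, "ca1_pyr": n_pyr, "ca1_int": n_int}
    params, slices = _param_arrays(n_per_pop)
    N = sum(n_per_pop.values())
    ws = cfg.weight_scale
    dt = cfg.dt_ms
    W_ampa = np.zeros((N, N))
    W_gaba = np.zeros((N, N))
    for spec in OFFLINE_SYNAPSES:
        pre_sl, post_sl = slices[spec.pre], slices[spec.post]
        if spec.weight_nS == "STDP":
            w = (w33_norm if spec.post == "ca3_pyr" else w31_norm) * w_max_nS * ws
        else:
            mask = random_connectivity(
                pre_sl.stop - pre_sl.start, post_sl.stop - post_sl.start,
                cfg.conn_p(spec.p_connect), rng, no_self=spec.pre == spec.post,
            )
            w = mask * float(spec.weight_nS) * ws
        target = W_ampa if spec.E_rev_mV == E_AMPA_MV else W_gaba
        target[pre_sl, post_sl] += w
    delay_steps = max(1, int(round(1.0 / dt)))
    channels = [
        _Channel("ampa", 1.0, 9.0, E_AMPA_MV, delay_steps, W_ampa),
        _Channel("gaba", 0.3, 3.0, E_GABA_MV, delay_steps, W_gaba),
        _Channel("dg", DG_RISE_MS, DG_DECAY_MS, E_AMPA_MV,
                 max(1, int(round(DG_DELAY_MS / dt))), None),
    ]
    dg_mask = np.zeros(N, dtype=bool)
    sl3 = slices["ca3_pyr"]
    dg_mask[sl3] = rng.random(n_pyr) < cfg.conn_p(DG_P_CONNECT)
    n_lfp = min(cfg.lfp.n_sampled_cells, n_pyr)
    lfp_cells = slices["ca1_pyr"].start + rng.choice(n_pyr, size=n_lfp, replace=False)
    return OfflineNetwork(cfg, pfm_ca3, pfm_ca1, channels, dg_mask, params,
                          slices, lfp_cells)


@dataclass
class SimResult:
    spike_times_ms: np.ndarray
    spike_ids: np.ndarray
    lfp_mV: np.ndarray
    lfp_fs_hz: float
    duration_s: float


def simulate_offline(
    net: OfflineNetwork,
    duration_s: float,
    cue_center_cm: float | None = None,
    cue_t_ms: float = 100.0,
    seed: int = 0,
    external_current_pA: np.ndarray | None = None,
) -> SimResult:
    """Forward-Euler integration of the offline network.

    Spontaneous mode (``cue_center_cm is None``) drives CA3 with the
    15 nS dentate background; cued mode lowers the background to 10 nS
    and delivers a 20 ms, 30 Hz Poisson burst at 80 nS to CA3 place cells
    whose field centers lie within a 20 cm window around the cue center.
    """
    cfg = net.cfg
    dt = cfg.dt_ms
    n_steps = int(round(duration_s * 1e3 / dt))
    rng = np.random.default_rng(seed)
    N = net.n_total
    p = net.params
    V = p["E_L"].copy()
    w_ad = np.zeros(N)
    refr = np.zeros(N, dtype=int)
    refr_steps = np.round(p["t_ref"] / dt).astype(int)
    # conductance channel states and delay ring buffers
    states = []
    for ch in net.channels:
        states.append({
            "a": np.zeros(N),
            "r": np.zeros(N),
            "da": np.exp(-dt / ch.tau_decay_ms),
            "dr": np.exp(-dt / ch.tau_rise_ms),
            "norm": _biexp_norm(ch.tau_rise_ms, ch.tau_decay_ms),
            "buf": np.zeros((ch.delay_steps, N)),
            "ch": ch,
        })
    dg_state = states[2]
    # dentate background: an independent 12 Hz realization per connected
    # cell (generator semantics), so intra-cell EPSP coincidences occur
    dg_weight = DG_WEIGHT_SPONTANEOUS_NS if cue_center_cm is None else DG_WEIGHT_CUED_NS
    dg_cells = np.nonzero(net.dg_mask)[0]
    n_per_cell = rng.poisson(DG_RATE_HZ * duration_s, len(dg_cells))
    dg_steps = np.concatenate([
        rng.integers(0, n_steps, n) for n in n_per_cell
    ]) if len(dg_cells) else np.empty(0, dtype=int)
    dg_cell_ids = np.repeat(dg_cells, n_per_cell)
    order = np.argsort(dg_steps, kind="stable")
    dg_steps, dg_cell_ids = dg_steps[order], dg_cell_ids[order]
    # cue burst: per-target independent Poisson trains
    cue_events: dict[int, np.ndarray] = {}
    if cue_center_cm is not None:
        centers = net.pfm_ca3.centers_cm
        sl3 = net.slices["ca3_pyr"]
        targets = np.nonzero(net.pfm_ca3.is_place
                             & (np.abs(centers - cue_center_cm) <= CUE_WINDOW_CM / 2))[0]
        if len(targets) == 0:
            raise ValueError("no place cells in the cue window")
        for tgt in targets:
            n_sp = rng.poisson(CUE_RATE_HZ * CUE_DURATION_MS / 1e3)
            for t_sp in cue_t_ms + rng.uniform(0, CUE_DURATION_MS, n_sp):
                step = int(round(t_sp / dt))
                cue_events.setdefault(step, []).append(sl3.start + tgt)  # type: ignore[arg-type]
        cue_events = {s: np.array(v) for s, v in cue_events.items()}
    record_every = max(1, int(round(1e3 / cfg.lfp.fs_hz / dt)))
    lfp = np.zeros(n_steps // record_every + 1)
    lfp_factor = 1e-12 / (4 * np.pi * cfg.lfp.sigma_ext_S_per_m
                          * cfg.lfp.r_um * 1e-6) * 1e3  # nS*mV -> mV
    spike_t: list[np.ndarray] = []
    spike_i: list[np.ndarray] = []
    dg_ptr = 0
    exp_clip = 20.0
    for step in range(n_steps):
        # deliver scheduled conductance events
        for st in states:
            slot = step % st["ch"].delay_steps
            inc = st["buf"][slot]
            st["a"] *= st["da"]
            st["r"] *= st["dr"]
            np.add(st["a"], inc * st["norm"], out=st["a"])
            np.add(st["r"], inc * st["norm"], out=st["r"])
            inc[:] = 0.0
        # schedule dentate background
        while dg_ptr < len(dg_steps) and dg_steps[dg_ptr] == step:
            slot = step % dg_state["ch"].delay_steps
            dg_state["buf"][slot, dg_cell_ids[dg_ptr]] += dg_weight
            dg_ptr += 1
        if cue_events and step in cue_events:
            slot = step % dg_state["ch"].delay_steps
            np.add.at(dg_state["buf"][slot], cue_events[step], CUE_WEIGHT_NS)
        # synaptic current (pA) = sum_c g_c (V - E_c)
        I_syn = np.zeros(N)
        for st in states:
            g = st["a"] - st["r"]
            I_syn += g * (V - st["ch"].E_mV)
        if external_current_pA is not None:
            I_syn -= external_current_pA
        exp_arg = np.clip((V - p["theta"]) / p["Delta_T"], None, exp_clip)
        dV = (-p["g_L"] * (V - p["E_L"]) + p["g_L"] * p["Delta_T"] * np.exp(exp_arg)
              - I_syn - w_ad) * (dt / p["C_m"])
        dw = (p["a"] * (V - p["E_L"]) - w_ad) * (dt / p["tau_w"])
        active = refr == 0
        V = np.where(active, V + dV, p["V_reset"])
        w_ad += dw
        refr = np.maximum(refr - 1, 0)
        spiking = np.nonzero(active & (V >= p["V_peak"]))[0]
        if len(spiking):
            V[spiking] = p["V_reset"][spiking]
            w_ad[spiking] += p["b"][spiking]
            refr[spiking] = refr_steps[spiking]
            spike_t.append(np.full(len(spiking), step * dt))
            spike_i.append(spiking)
            for st in states:
                W = st["ch"].W
                if W is None:
                    continue
                slot = step % st["ch"].delay_steps
                st["buf"][slot] += W[spiking].sum(axis=0)
        if step % record_every == 0:
            idx = net.lfp_cells
            tot = 0.0
            for st in states:
                g = st["a"][idx] - st["r"][idx]
                tot += np.sum(g * (V[idx] - st["ch"].E_mV))
            lfp[step // record_every] = lfp_factor * tot
    times = np.concatenate(spike_t) if spike_t else np.empty(0)
    ids = np.concatenate(spike_i) if spike_i else np.empty(0, dtype=int)
    return SimResult(spike_times_ms=times, spike_ids=ids,
                     lfp_mV=lfp[: n_steps // record_every],
                     lfp_fs_hz=cfg.lfp.fs_hz, duration_s=duration_s)
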