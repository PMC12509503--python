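"""End-to-end replay experiments: train with STDP, then probe offline.

Three training regimes mirror the IS patterns seen in vivo:

* ``control``      -- no IS input during exploration;
* ``clustered``    -- IS delivered at the fixed +/-100 cm reference point
                      (high spatial information);
* ``dispersed``    -- IS location drawn uniformly along the traversed arm
                      on each trial (low spatial information).

After training, the learned pyramidal weights parameterize the offline
network, which is probed either spontaneously (replay statistics,
spectra) or with cues at increasing distance from the reference point
(contamination sweep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import contamination, detect_replays, spectral_peak_hz, spectral_summary
from .exploration import simulate_exploration
from .network import OfflineNetwork, build_offline_network, simulate_offline
from .params import (
    CA3_CA1_STDP,
    CA3_CA3_STDP,
    IsStimConfig,
    NetworkConfig,
    PlaceFieldMap,
)
from .stdp import initial_weights, random_connectivity, train_stdp

__all__ = ["TrainedNetwork", "train_network", "spontaneous_replay_summary",
           "cue_contamination", "cue_sweep"]

CONDITIONS = {
    "control": IsStimConfig(mode="off"),
    # spontaneous-dynamics comparison: IS spikes broadcast to all CA3
    # pyramidal cells (1% per-spike delivery), the pathological regime
    "epileptic": IsStimConfig(mode="clustered", delivery="broadcast"),
    # cue comparison: delivery restricted to currently active place cells
    "clustered": IsStimConfig(mode="clustered"),
    "dispersed": IsStimConfig(mode="dispersed"),
}


@dataclass
class TrainedNetwork:
    condition: str
    cfg: NetworkConfig
    pfm_ca3: PlaceFieldMap
    pfm_ca1: PlaceFieldMap
    w33: np.ndarray
    w31: np.ndarray
    seed: int

    def build(self, seed_offset: int = 0) -> OfflineNetwork:
        return build_offline_network(
            self.w33, self.w31, self.cfg, self.pfm_ca3, self.pfm_ca1,
            seed=self.seed + 7919 * (seed_offset + 1),
        )


def train_network(
    condition: str,
    cfg: NetworkConfig | None = None,
    duration_s: float = 300.0,
    seed: int = 0,
) -> TrainedNetwork:
    """Exploration + STDP for one regime; returns frozen weights."""
    if cfg is None:
        cfg = NetworkConfig()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    n = cfg.n_pyr
    pfm_ca3 = PlaceFieldMap.random(n, rng)
    pfm_ca1 = PlaceFieldMap.random(n, rng)
    expl = simulate_exploration(
        pfm_ca3, pfm_ca1, CONDITIONS[condition],
        duration_s=duration_s, seed=seed + 1,
    )
    p_pyr = cfg.conn_p(0.1)
    mask33 = random_connectivity(n, n, p_pyr, rng, no_self=True)
    mask31 = random_connectivity(n, n, p_pyr, rng)
    # initial weights are specified in nS (0.3 / 0.7 nS medians), i.e. a
    # small fraction of w_max on the normalized scale
    w33_0 = initial_weights(mask33, 0.3 / CA3_CA3_STDP.w_max_nS, rng)
    w31_0 = initial_weights(mask31, 0.7 / CA3_CA1_STDP.w_max_nS, rng)
    t3, i3 = expl.spikes["ca3_pyr"]
    t1, i1 = expl.spikes["ca1_pyr"]
    w33 = train_stdp(t3, i3, t3, i3, mask33, w33_0, CA3_CA3_STDP, recurrent=True)
    w31 = train_stdp(t3, i3, t1, i1, mask31, w31_0, CA3_CA1_STDP)
    return TrainedNetwork(condition=condition, cfg=cfg, pfm_ca3=pfm_ca3,
                          pfm_ca1=pfm_ca1, w33=w33, w31=w31, seed=seed)


def spontaneous_replay_summary(
    trained: TrainedNetwork, duration_s: float = 5.0, seed: int = 0
) -> dict:
    """Spontaneous offline run: replay windows plus spectral summary."""
    net = trained.build(seed_offset=seed)
    sim = simulate_offline(net, duration_s, seed=seed)
    windows = detect_replays(sim.lfp_mV, sim.lfp_fs_hz)
    summary = spectral_summary(sim.lfp_mV, sim.lfp_fs_hz, replay_windows=windows)
    return {
        "sim": sim,
        "replay_windows": windows,
        "n_replays": len(windows),
        "spectral_peak_hz": spectral_peak_hz(summary),
        "summary": summary,
    }


def cue_contamination(
    trained: TrainedNetwork,
    cue_distance_cm: float,
    cued_arm_sign: float = 1.0,
    seed: int = 0,
    duration_s: float = 1.0,
    cue_t_ms: float = 200.0,
) -> dict:
    """Cue at ``reference - distance`` (toward the maze center) and count
    contaminating spikes on the un-cued arm around the evoked event."""
    net = trained.build(seed_offset=seed)
    center = cued_arm_sign * (CONDITIONS["clustered"].reference_cm - cue_distance_cm)
    sim = simulate_offline(net, duration_s, cue_center_cm=center,
                           cue_t_ms=cue_t_ms, seed=seed)
    # analysis window: replay detected after the cue, else a fixed window
    windows = [w for w in detect_replays(sim.lfp_mV, sim.lfp_fs_hz)
               if w[1] > cue_t_ms / 1e3]
    if windows:
        window = windows[0]
    else:
        window = (cue_t_ms / 1e3, cue_t_ms / 1e3 + 2 * 0.150)
    centers = np.full(net.n_total, np.nan)
    centers[net.slices["ca3_pyr"]] = trained.pfm_ca3.centers_cm
    centers[net.slices["ca1_pyr"]] = trained.pfm_ca1.centers_cm
    n_contam = contamination(sim.spike_times_ms / 1e3, sim.spike_ids,
                             centers, cued_arm_sign, window)
    return {"contamination": n_contam, "window": window, "sim": sim}


def cue_sweep(
    trained_nets: list[TrainedNetwork],
    distances_cm=(0.0, 20.0, 40.0, 60.0, 80.0),
    seeds_per_net: int = 5,
    duration_s: float = 1.0,
) -> dict[float, list[int]]:
    """Contamination per cue distance pooled over networks and seeds."""
    out: dict[float, list[int]] = {float(d): [] for d in distances_cm}
    for d in distances_cm:
        for k, tn in enumerate(trained_nets):
            for s in range(seeds_per_net):
                res = cue_contamination(tn, d, seed=1000 * k + s,
                                        duration_s=duration_s)
                out[float(d)].append(res["contamination"])
    return out
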