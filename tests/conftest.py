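"""Shared fixtures.

The expensive BD simulations are session-scoped and shared across the unit
and acceptance tests: an equilibrated N=64 chain ensemble (bond-length
statistics), a free-chain persistence-length study, and the scaled N=256
compression study (equilibrium scales + steady states at four gasket
speeds).
"""

from __future__ import annotations

import numpy as np
import pytest

from nanodozer import (ChannelGasket, ForceFieldParams, RunPlan, advance,
                       compress, equilibrate, init_chain)


@pytest.fixture(scope="session")
def equilibrated_n64():
    """Equilibrated N=64 confined-chain frame sets for kappa in {0, 3.2}.

    300 snapshots of equilibration, then 200 snapshots sampled at default
    force-field parameters (T=1.2, gamma=0.7, k=30, R0=1.5, dt=0.01).
    """
    out = {}
    chan = ChannelGasket(gasket_enabled=False)
    for kappa in (0.0, 3.2):
        params = ForceFieldParams(kappa=kappa)
        st = init_chain(64, chan, params, seed=11)
        frames = []
        for i in range(500):
            st = advance(st, params, chan, 1000, seed=90_000 + i)
            if i >= 300:
                frames.append(st.copy())
        out[kappa] = frames
    return out


@pytest.fixture(scope="session")
def lp_study():
    """Free-chain persistence lengths for kappa in {2, 4, 8}, 3 replicas.

    Chains start from equilibrium self-avoiding worm-like-chain draws, so
    only local excluded-volume relaxation remains before sampling.
    """
    from nanodozer import persistence_length

    out = {}
    for kappa in (2.0, 4.0, 8.0):
        params = ForceFieldParams(kappa=kappa)
        lps = []
        for rep in range(3):
            st = init_chain(128, None, params, seed=11 + rep,
                            conformation="wlc")
            frames = []
            for i in range(240):
                st = advance(st, params, None, 1000,
                             seed=int(kappa * 1000) + 7777 * rep + i)
                if i >= 40 and i % 2 == 0:
                    frames.append(st.positions.copy())
            lps.append(persistence_length(frames))
        out[kappa] = float(np.mean(lps))
    return out


@pytest.fixture(scope="session")
def compression_study():
    """Scaled squeezing study: N=256, D=16, four gasket speeds.

    One long equilibration fixes the normalization scales (r0, c0); the
    same equilibrated state is then compressed at speeds spanning a factor
    of 8 around the reference 0.05 bond-lengths/snapshot, each run to
    steady state with independent noise.
    """
    plan0 = RunPlan(n_beads=256, base_seed=21,
                    max_equil_snapshots=2500, min_equil_snapshots=600,
                    equil_sample_snapshots=600)
    state, summary = equilibrate(plan0, seed=21)
    # fixed run lengths sized from the diffusive settling time of the
    # compressed region (slower compression needs longer to converge)
    durations = {0.025: 3000, 0.05: 1600, 0.1: 1300, 0.2: 1000}
    runs = {}
    for v, n_snap in durations.items():
        plan = RunPlan(n_beads=256, base_seed=21, v_push=v,
                       max_compress_snapshots=n_snap,
                       steady_extra_snapshots=10**6)
        runs[v] = compress(state, plan, seed=int(v * 1e4))
    # short replicas at the fast speed for ensemble-averaged shock
    # tracking (same start, independent noise; the long v=0.1 run is the
    # fourth ensemble member)
    shock_members = []
    for k in range(3):
        plan = RunPlan(n_beads=256, base_seed=21, v_push=0.1,
                       max_compress_snapshots=600,
                       steady_extra_snapshots=10**6)
        shock_members.append(compress(state, plan, seed=7000 + k))
    return {"summary": summary, "runs": runs,
            "shock_members": shock_members,
            "r0": summary.r0, "c0": summary.c0, "n_beads": 256}
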