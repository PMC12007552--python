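"""Shared fixtures.

The heavy end-to-end computations (beamformer localisation sweep,
planted-connectome structure recovery, multi-subject fingerprinting) are
session-scoped so several tests can interrogate one run.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

from opmconn.bands import BandDefinition
from opmconn.datatypes import Connectome, PipelineConfig
from opmconn.pipeline import process_run, run_pipeline
from opmconn.preprocess import Preprocessor
from opmconn.beamformer import LCMVBeamformer
from opmconn.reliability import upper_triangle
from opmconn.simulate import (
    SimulationSpec,
    add_noise_and_interference,
    dipole_orientations,
    make_parcels,
    make_sensor_array,
    project_to_sensors,
    random_coupling_matrix,
    simulate_dataset,
    simulate_run,
    simulate_sources,
)


@pytest.fixture(scope="session")
def alpha_band() -> BandDefinition:
    return BandDefinition("alpha", 8.0, 12.0)


def random_connectome(P: int, rng: np.random.Generator, **meta) -> Connectome:
    m = rng.uniform(0.0, 0.5, size=(P, P))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return Connectome(values=m, band=meta.pop("band", "alpha"), **meta)


@pytest.fixture(scope="session")
def localisation_results(alpha_band):
    """50 single-source repetitions: recovered parcel + unit-gain errors.

    One active parcel out of 20 per repetition, 30-s runs at the default
    sensor noise floor and interference level (no artifact epochs or dead
    channels, so the localisation statistic is isolated).
    """
    P, n_sens, dur = 20, 16, 30.0
    array = make_sensor_array(n_sens, 0.10)
    parcels = make_parcels(P, 0.09, seed=1)
    hits, gain_errors = [], []
    for rep in range(50):
        rng = np.random.default_rng(1000 + rep)
        true_p = rep % P
        spec = SimulationSpec(
            n_parcels=P, n_sensors=n_sens, duration_s=dur, seed=rep,
            artifact_epoch_rate=0.0, dead_channel_rate=0.0,
        )
        src, _ = simulate_sources(spec, 0, 0)
        sources = np.zeros_like(src)
        sources[true_p] = src[true_p]
        ori = dipole_orientations(parcels, seed=rep)
        rec = project_to_sensors(sources, parcels, array, ori, spec.fs)
        rec, _ = add_noise_and_interference(rec, spec, rng, array=array)
        pre = Preprocessor()
        clean = pre.fit_transform(rec, array)
        bf = LCMVBeamformer(band=alpha_band, sensor_projector=pre.projector_)
        s = bf.fit_transform(clean, parcels, array)
        hits.append(int(np.argmax(s.var(axis=1))) == true_p)
        gains = np.einsum(
            "pn,pn->p", bf.weights_,
            np.einsum("pnk,pk->pn", bf.leadfields_, bf.orientations_),
        )
        gain_errors.append(np.abs(gains - 1.0).max())
    return {"hits": np.array(hits), "gain_errors": np.array(gain_errors)}


@pytest.fixture(scope="session")
def structure_recovery(alpha_band):
    """End-to-end planted-connectome recovery: 20 parcels, 600-s runs.

    Coupling entries drawn from {0, 0.3, 0.6}; both runs of one subject are
    pushed through the full preprocess -> beamform -> AEC chain and the
    recovered upper triangles are rank-compared with the planted coupling.
    """
    P = 20
    C = random_coupling_matrix(P, seed=0)
    spec = SimulationSpec(
        n_parcels=P, n_sensors=25, duration_s=600.0, coupling=C, seed=0
    )
    cfg = PipelineConfig(bands=[alpha_band])
    rhos = []
    for run in (0, 1):
        rec, array, parcels, _ = simulate_run(spec, 0, run)
        conns = process_run(rec, array, parcels, cfg)
        rhos.append(
            spearmanr(
                upper_triangle(conns["alpha"]), upper_triangle(C)
            ).statistic
        )
    return {"spearman_per_run": rhos, "coupling": C}


@pytest.fixture(scope="session")
def fingerprint_pipeline(alpha_band):
    """Full pipeline over 5 two-run subjects with distinct planted connectomes."""
    spec = SimulationSpec(
        n_subjects=5, n_parcels=15, n_sensors=20, duration_s=150.0, seed=0
    )
    recs, array, parcels, truths = simulate_dataset(spec)
    cfg = PipelineConfig(
        bands=[alpha_band], permutation_iters=2000, rng_seed=0
    )
    result = run_pipeline(cfg, recs, array, parcels)
    return {"result": result, "truths": truths, "n_subjects": 5}
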