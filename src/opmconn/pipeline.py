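"""End-to-end orchestration: preprocess -> beamform -> connectome -> reliability.

Every subject contributes exactly two runs. Per run, the recording is
preprocessed once (filters, channel/epoch rejection, HFC); per band, an
LCMV beamformer is fitted on that band's covariance and the projected
parcel series are turned into a normalised orthogonalised-AEC connectome.
The reliability stage then compares runs within and between subjects per
band. The whole pipeline is a deterministic function of (inputs, config,
seed).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .beamformer import LCMVBeamformer
from .connectome import AECConnectome, global_connectivity
from .datatypes import Connectome, ParcelSet, PipelineConfig, Recording, SensorArray
from .preprocess import Preprocessor
from .reliability import BandReliability, ReliabilityAnalysis

__all__ = ["PipelineResult", "process_run", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline computes, keyed by band."""

    config: PipelineConfig
    connectomes: dict[str, dict[str, dict[str, Connectome]]]  # band -> subject -> run
    reliability: dict[str, BandReliability]
    global_connectivity: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )

    def to_dict(self) -> dict:
        return {
            "bands": list(self.reliability),
            "reliability": {b: r.to_dict() for b, r in self.reliability.items()},
            "global_connectivity": self.global_connectivity,
        }


def process_run(
    rec: Recording,
    array: SensorArray,
    parcels: ParcelSet,
    config: PipelineConfig,
) -> dict[str, Connectome]:
    """Preprocess one run and build a normalised connectome per band."""
    pre = Preprocessor(
        notch_freq=config.notch_freq,
        notch_q=config.notch_q,
        bp_lo=config.bp_lo,
        bp_hi=config.bp_hi,
        epoch_length_s=config.epoch_length_s,
        sd_thresh=config.epoch_flag_sd,
        min_channels=config.epoch_flag_min_channels,
    )
    clean = pre.fit_transform(rec, array)
    out: dict[str, Connectome] = {}
    for band in config.bands:
        band.validate_against_fs(rec.fs)
        bf = LCMVBeamformer(
            band=band,
            reg_fraction=config.reg_fraction,
            sensor_projector=pre.projector_,
        )
        sources = bf.fit_transform(clean, parcels, array)
        conn = AECConnectome(
            fs=rec.fs,
            envelope_fs=config.envelope_fs,
            band=band.name,
            normalise=False,
        ).transform(sources, subject=rec.subject_id, run=rec.run_id)
        out[band.name] = conn
    return out


def run_pipeline(
    config: PipelineConfig,
    recordings: list[Recording],
    array: SensorArray,
    parcels: ParcelSet,
) -> PipelineResult:
    """Run the full analysis over a list of two-run subjects.

    Recordings are grouped by ``subject_id``; each subject must contribute
    exactly two runs (ordered by ``run_id``). Raw connectomes feed the
    global-connectivity summaries; normalised copies feed the reliability
    statistics.
    """
    by_subject: dict[str, list[Recording]] = defaultdict(list)
    for rec in recordings:
        by_subject[rec.subject_id].append(rec)
    for sid, recs in by_subject.items():
        if len(recs) != 2:
            raise ValueError(
                f"subject {sid!r} has {len(recs)} runs; the design requires exactly 2"
            )
    subjects = sorted(by_subject)

    from .connectome import normalize_connectome

    connectomes: dict[str, dict[str, dict[str, Connectome]]] = defaultdict(
        lambda: defaultdict(dict)
    )
    gc: dict[str, dict[str, dict[str, float]]] = defaultdict(lambda: defaultdict(dict))
    for sid in subjects:
        for rec in sorted(by_subject[sid], key=lambda r: r.run_id):
            per_band = process_run(rec, array, parcels, config)
            for band_name, conn in per_band.items():
                connectomes[band_name][sid][rec.run_id] = conn
                gc[band_name][sid][rec.run_id] = global_connectivity(conn)

    by_band: dict[str, tuple[list[Connectome], list[Connectome]]] = {}
    for band_name, per_subject in connectomes.items():
        run_ids = sorted(next(iter(per_subject.values())))
        run1 = [
            normalize_connectome(per_subject[s][run_ids[0]]) for s in subjects
        ]
        run2 = [
            normalize_connectome(per_subject[s][run_ids[1]]) for s in subjects
        ]
        by_band[band_name] = (run1, run2)

    rel = ReliabilityAnalysis(
        permutation_iters=config.permutation_iters,
        seed=config.rng_seed,
        subsample=len(subjects) >= 3,
    ).fit(by_band)

    return PipelineResult(
        config=config,
        connectomes={b: dict(v) for b, v in connectomes.items()},
        reliability=rel.report_,
        global_connectivity={b: {s: dict(r) for s, r in v.items()} for b, v in gc.items()},
    )
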