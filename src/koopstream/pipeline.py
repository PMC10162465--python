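"""End-to-end orchestration of the feature-extraction pipeline.

Stage order: preprocess -> delay embedding -> diffusion maps -> dictionary
selection -> eDMD -> spectral branches -> phase prediction -> (optional)
behavior-aware statistics.  Everything up to and including the location of
phi_star uses the neural data alone; behavioral inputs enter only for
orienting phi_star, aligning predictions with button presses, and the
percept statistics.  When no timeline is supplied those stages are skipped
with warnings and the neural-only results are still returned.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import branches as br
from . import diffusion, edmd, phase, preprocess, stats
from .config import PipelineConfig
from .datatypes import (BranchAssignment, DiffusionBasis, DelayMatrix,
                        KoopmanDecomposition, KoopstreamError,
                        PerceptTimeline, Recording, SwitchPrediction,
                        TripletLabels)
from .delays import build_delay_coordinates

__all__ = ["PipelineResult", "run_pipeline", "select_prediction_oscillator"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Bundle of every stage artifact from one pipeline run."""

    config: PipelineConfig
    preprocessed: Recording
    delay: DelayMatrix
    basis: DiffusionBasis
    dictionary_cutoff: int
    decomposition: KoopmanDecomposition
    branches: BranchAssignment
    phi_star: np.ndarray
    prediction: SwitchPrediction | None = None
    labels: TripletLabels | None = None
    permutation: dict | None = None
    kl_divergence: float | None = None
    oriented: bool = False
    timings: dict = field(default_factory=dict)


def select_prediction_oscillator(decomp: KoopmanDecomposition,
                                 branch_assignment: BranchAssignment
                                 ) -> tuple[int, float]:
    """Leading J2 oscillator for switch prediction.

    The first J2 eigenfunction with positive frequency (J2 entries are
    already ordered by decreasing real part through the decomposition
    ordering); the reference frequency is the nearest triplet-rate
    harmonic.
    """
    osc = [j for j in branch_assignment.J2 if decomp.frequencies[j] > 0]
    if not osc:
        raise KoopstreamError("branch J2 has no oscillatory eigenfunction")
    lead = min(osc)  # decomposition indices are sorted by decreasing Re
    f_raw = decomp.frequencies[lead]
    m = max(1, int(round(f_raw / branch_assignment.f_triplet)))
    return lead, m * branch_assignment.f_triplet


def run_pipeline(rec: Recording, config: PipelineConfig | None = None,
                 timeline: PerceptTimeline | None = None) -> PipelineResult:
    """Execute the full pipeline on a recording.

    ``timeline`` is optional: the feature extraction itself is agnostic to
    behavior, which only enters the orientation of phi_star, press/window
    alignment, and percept statistics.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = time.perf_counter() - t0
            log.info("stage %-12s %.2f s", name, timings[name])
        return done

    try:
        done = _stage("preprocess")
        pp = preprocess.preprocess(rec, config.std_window_s,
                                   config.smooth_ms, config.target_rate)
        done()

        done = _stage("embed")
        dm = build_delay_coordinates(pp, config.s, config.alpha)
        done()

        done = _stage("diffusion")
        basis = diffusion.diffusion_basis(dm, config.kmin, config.knn,
                                          config.n_eigs,
                                          config.squared_bandwidth,
                                          theiler=config.theiler)
        done()

        done = _stage("edmd")
        cutoff, _diag = edmd.select_dictionary(
            basis, config.f_triplet, config.target_rate,
            config.tol_f, config.theta, config.run_length)
        decomp = edmd.run_edmd(basis.eigvecs[:, :cutoff], dm.dt,
                               times=dm.times)
        edmd.compute_modes(pp, decomp)
        done()

        done = _stage("branches")
        assignment = br.organize_spectrum(decomp, config.f_triplet,
                                          config.tol_f, config.tol_real)
        phi_star = br.phi_star_series(decomp, assignment)
        done()
    except KoopstreamError as err:
        raise KoopstreamError(
            f"pipeline stage failed: {err} "
            f"[config: {config.to_json()}]") from err

    result = PipelineResult(config=config, preprocessed=pp, delay=dm,
                            basis=basis, dictionary_cutoff=cutoff,
                            decomposition=decomp, branches=assignment,
                            phi_star=phi_star, timings=timings)

    # --- behavior-aware tail -------------------------------------------
    rt = timeline.reaction_time if timeline is not None else config.rt

    done = _stage("predict")
    lead, f_pred = select_prediction_oscillator(decomp, assignment)
    button_times = timeline.button_times if timeline is not None else None
    result.prediction = phase.build_switch_prediction(
        decomp.eigfuns[:, lead], f_pred, decomp.times, rt,
        button_times=button_times)
    done()

    if timeline is None:
        warnings.warn("no behavioral timeline; orientation and percept "
                      "statistics skipped", RuntimeWarning, stacklevel=2)
        return result

    done = _stage("stats")
    labels = stats.label_triplets(timeline)
    sample_labels = labels.sample_labels(decomp.times)
    phi_star, oriented = br.orient_phi_star(phi_star, sample_labels)
    result.phi_star = phi_star
    result.oriented = oriented
    result.labels = labels
    result.permutation = stats.permutation_test_phi_star(
        phi_star, decomp.times, labels, config.n_perm, config.stats_seed)
    result.kl_divergence = stats.kl_divergence_percepts(
        phi_star, decomp.times, labels, config.n_bins)
    done()
    return result


def save_results(result: PipelineResult, outdir) -> None:
    """Persist the run: config, branch table, prediction events, summary."""
    import json

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(result.config.to_json())

    d = result.decomposition
    a = result.branches
    branch_of = {}
    for j in a.J1:
        branch_of[j] = "J1"
    for j in a.J2:
        branch_of[j] = "J2"
    pd.DataFrame({
        "index": np.arange(d.n_eigs),
        "re_omega": d.decay_rates,
        "freq_hz": d.frequencies,
        "branch": [branch_of.get(j, "") for j in range(d.n_eigs)],
        "harmonic": [a.harmonic_of.get(j, "") for j in range(d.n_eigs)],
    }).to_csv(outdir / "branches.tsv", sep="\t", index=False)

    if result.prediction is not None:
        p = result.prediction
        events = pd.DataFrame({
            "predicted_time": p.predicted_times,
            "window_start": p.windows[:, 0] if len(p.windows) else [],
            "window_end": p.windows[:, 1] if len(p.windows) else [],
        })
        events.to_csv(outdir / "predicted_switches.tsv", sep="\t",
                      index=False)
        if p.matches is not None:
            p.matches.to_csv(outdir / "press_alignment.tsv", sep="\t",
                             index=False)

    summary = {
        "dictionary_cutoff": result.dictionary_cutoff,
        "phi_star_index": a.phi_star_index,
        "omega_star": a.omega_star,
        "oriented": result.oriented,
        "kl_divergence": result.kl_divergence,
        "timings_s": result.timings,
    }
    if result.permutation is not None:
        summary["permutation_p"] = result.permutation["p"]
        summary["mu_obs"] = result.permutation["mu_obs"]
    if result.prediction is not None:
        summary["bp"] = result.prediction.bp
        summary["pb"] = result.prediction.pb
        if result.prediction.bp is not None:
            chi, pval = phase.chi_square_order_test(
                result.prediction.bp, result.prediction.pb) \
                if result.prediction.bp + result.prediction.pb > 0 \
                else (None, None)
            summary["chi2"] = chi
            summary["chi2_p"] = pval
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    embed = stats.export_embedding(d, a, result.labels)
    embed.to_csv(outdir / "embedding3d.tsv", sep="\t", index=False)
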