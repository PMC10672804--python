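"""Cohort-level orchestration: detect -> couple -> score -> link.

``run_pipeline`` drives the full analysis over a cohort of recordings
(read from disk or generated on the fly), writing per-recording event
tables, spectra, PETH/KL outputs and time-frequency contrasts, the cohort
maturity table, and the PLSC and GLMM linking results, together with a
machine-readable provenance log of every parameter and seed used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, events, io, linking, maturity, spectral, synth
from .recording import Recording
from .synth import CohortSpec, GeneratorConfig, GroundTruth


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis with their standard defaults.

    ``n_perm``/``n_boot`` default to the full 5000; ``ci_profile`` drops
    them to 500 for quick runs and flags that in the provenance log.
    """

    output_dir: str = "results"
    spindle_channel_set: str = "centro-parietal"
    frontal_channel_set: str = "frontal"
    so_channel_set: str = "frontal"
    adult_band_hz: tuple[float, float] = events.ADULT_LIKE_BAND
    band_half_width_hz: float = 1.5
    fallback_peak_hz: float = 12.0
    n_shuffles: int = 1000
    n_perm: int = 5000
    n_boot: int = 5000
    seed: int = 0
    ci_profile: bool = False
    cohort: CohortSpec | list | None = None
    manifest: str | None = None

    def effective_counts(self) -> tuple[int, int]:
        if self.ci_profile:
            return 500, 500
        return self.n_perm, self.n_boot


@dataclass
class SubjectResult:
    subject_id: str
    peak_hz: float | None
    band: tuple[float, float]
    dev_spindles: list
    adult_spindles: list
    sos_frontal: list
    sos_cp: list
    peth: coupling.PETH | None
    tf: coupling.TFContrast | None
    summaries: dict = field(default_factory=dict)
    spectrum_table: pd.DataFrame | None = None


def _load_manifest(manifest_path: str) -> list[tuple[str, Recording]]:
    manifest = yaml.safe_load(Path(manifest_path).read_text())
    out = []
    base = Path(manifest_path).parent
    for entry in manifest["recordings"]:
        sid = entry["subject_id"]
        for key in ("edf", "hypnogram", "artifacts"):
            if key not in entry:
                raise ValueError(f"manifest entry {sid}: missing {key!r}")
            if not (base / entry[key]).exists():
                raise FileNotFoundError(
                    f"recording {sid}: missing {key} file {entry[key]!r}"
                )
        rec = io.read_recording(
            base / entry["edf"], base / entry["hypnogram"], base / entry["artifacts"]
        )
        out.append((sid, rec))
    return out


def analyse_subject(
    subject_id: str,
    recording: Recording,
    config: PipelineConfig,
    seed: int,
) -> SubjectResult:
    """Single-recording pass: individual band, spindle + SO detection,
    PETH/KL and the SO-locked time-frequency contrast."""
    rng = np.random.default_rng(seed)
    cp = config.spindle_channel_set

    spec = spectral.nrem_power_spectrum(recording, cp)
    fit = spectral.fit_background(spec)
    corrected = spectral.correct_spectrum(spec, fit)
    peak = spectral.detect_peak(spec.freqs_hz, corrected, channel_set=cp)
    if peak is not None:
        band = events.individual_band(peak, config.band_half_width_hz)
        peak_hz = peak.peak_freq_hz
    else:
        # no dominant rhythm: fall back to a band centred on the cohort
        # reference peak, flagged via peak_hz = None
        band = events.Band(
            config.fallback_peak_hz - config.band_half_width_hz,
            config.fallback_peak_hz + config.band_half_width_hz,
        )
        peak_hz = None

    dev = events.detect_spindles(recording, cp, band[:2], spindle_class="development-specific")
    adult = events.detect_spindles(
        recording, cp, config.adult_band_hz, spindle_class="adult-like"
    )
    sos_f = events.detect_sos(recording, config.frontal_channel_set)
    sos_cp = events.detect_sos(recording, cp)
    sos_ref = sos_f if config.so_channel_set == config.frontal_channel_set else sos_cp

    minutes = recording.eligible_minutes(cp)
    summaries = {
        "dev_specific": events.summarize_features(dev, minutes, spindle_class="development-specific", topography=cp),
        "adult_like": events.summarize_features(adult, minutes, spindle_class="adult-like", topography=cp),
        "so_frontal": events.summarize_features(sos_f, recording.eligible_minutes(config.frontal_channel_set), topography="frontal"),
        "so_cp": events.summarize_features(sos_cp, minutes, topography=cp),
    }

    pe = None
    if adult and sos_ref:
        pe = coupling.peth_with_surrogate(
            adult, sos_ref, n_shuffles=config.n_shuffles, seed=rng
        )
    tf = None
    if sos_ref:
        try:
            so_tr, non_tr = coupling.extract_trials(recording, sos_ref, cp, seed=rng)
            tf = coupling.tf_contrast(so_tr, non_tr)
        except ValueError:
            tf = None
    return SubjectResult(
        subject_id=subject_id,
        spectrum_table=spectral.export_spectrum_table(spec, fit),
        peak_hz=peak_hz,
        band=(float(band[0]), float(band[1])),
        dev_spindles=dev,
        adult_spindles=adult,
        sos_frontal=sos_f,
        sos_cp=sos_cp,
        peth=pe,
        tf=tf,
        summaries=summaries,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full cohort analysis; returns the results directory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_perm, n_boot = config.effective_counts()

    if config.manifest is not None:
        pairs = _load_manifest(config.manifest)
    elif isinstance(config.cohort, CohortSpec):
        cohort, meta = synth.generate_cohort(config.cohort, int(rng.integers(2**31 - 1)))
        meta.to_csv(out_dir / "cohort_metadata.tsv", sep="\t", index=False)
        pairs = [(meta["subject_id"].iloc[i], rec) for i, (rec, _gt) in enumerate(cohort)]
    elif config.cohort is not None:  # explicit list of generator configs
        pairs = [
            (f"sub-{i:03d}", synth.generate_recording(c)[0])
            for i, c in enumerate(config.cohort)
        ]
    else:
        raise ValueError("PipelineConfig needs either a manifest or a cohort spec")

    subjects: list[SubjectResult] = []
    for sid, rec in pairs:
        try:
            res = analyse_subject(sid, rec, config, seed=int(rng.integers(2**31 - 1)))
        except Exception as err:  # noqa: BLE001 - abort names stage + recording
            raise RuntimeError(f"subject {sid}: analysis failed ({err})") from err
        subjects.append(res)
        events.events_to_frame(res.adult_spindles).to_csv(
            out_dir / f"{sid}_spindles_adult_like.tsv", sep="\t", index=False
        )
        events.events_to_frame(res.dev_spindles).to_csv(
            out_dir / f"{sid}_spindles_dev_specific.tsv", sep="\t", index=False
        )
        events.events_to_frame(res.sos_frontal).to_csv(
            out_dir / f"{sid}_sos_frontal.tsv", sep="\t", index=False
        )
        if res.spectrum_table is not None:
            res.spectrum_table.to_csv(out_dir / f"{sid}_spectrum.tsv", sep="\t", index=False)
        if res.tf is not None:
            np.savez_compressed(
                out_dir / f"{sid}_tf_contrast.npz",
                times_s=res.tf.times_s,
                freqs_hz=res.tf.freqs_hz,
                tmap=res.tf.tmap,
            )
        if res.peth is not None:
            pd.DataFrame(
                {
                    "bin_center_s": res.peth.bin_centers_s,
                    "observed_pct": res.peth.observed_pct,
                    "surrogate_pct": res.peth.surrogate_pct,
                }
            ).to_csv(out_dir / f"{sid}_peth.tsv", sep="\t", index=False)

    # ---- maturity table ------------------------------------------------
    rows = []
    for res in subjects:
        rows.append(
            {
                "subject_id": res.subject_id,
                "timepoint": 1,
                "adult_like": res.summaries["adult_like"],
                "dev_specific": res.summaries["dev_specific"],
                "so_amp_frontal_uv": res.summaries["so_frontal"].amplitude_uv,
                "so_amp_centroparietal_uv": res.summaries["so_cp"].amplitude_uv,
            }
        )
    mat = maturity.build_maturity_table(rows)
    kl = pd.Series(
        [res.peth.kl_divergence_nats if res.peth else np.nan for res in subjects],
        name="kl",
    )
    mat["kl"] = kl.to_numpy()
    mat.to_csv(out_dir / "maturity_table.tsv", sep="\t", index=False)

    # ---- group coupling tests ------------------------------------------
    results_summary: dict = {"n_subjects": len(subjects)}
    peths = [r.peth for r in subjects if r.peth is not None]
    if len(peths) >= 5:
        obs = np.stack([p.observed_pct for p in peths])
        sur = np.stack([p.surrogate_pct for p in peths])
        cres = coupling.cluster_test_peth(
            obs, sur, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        results_summary["peth_clusters"] = [
            {"sign": c.sign, "mass": c.cluster_mass, "p_doubled": c.p_value_doubled}
            for c in cres.clusters
        ]

    tfs = [r.tf for r in subjects if r.tf is not None]
    if len(tfs) >= 5:
        tf_res = coupling.cluster_test_tf(
            tfs, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        results_summary["tf_clusters"] = [
            {"sign": c.sign, "mass": c.cluster_mass, "p_doubled": c.p_value_doubled}
            for c in tf_res.significant
        ]

    # ---- linking -------------------------------------------------------
    complete = mat.dropna(subset=["spindle_maturity_component", "kl"])
    if len(tfs) == len(subjects) and len(complete) >= 10:
        X = complete[["freq_maturity_z", "density_maturity_z", "amp_maturity_z"]].to_numpy()
        Y = np.stack([subjects[i].tf.tmap.ravel() for i in complete.index])
        pres = linking.plsc(
            X, Y, n_perm=n_perm, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
        )
        pd.DataFrame(
            {
                "dimension": np.arange(pres.singular_values.size),
                "singular_value": pres.singular_values,
                "perm_p": pres.perm_p,
            }
        ).to_csv(out_dir / "plsc_dimensions.tsv", sep="\t", index=False)
        results_summary["plsc_perm_p"] = pres.perm_p.tolist()

    glmm_table = mat.dropna(subset=["kl"])
    if len(glmm_table) >= 10 and (glmm_table["kl"] > 0).all():
        model = linking.fit_modulation_model(glmm_table)
        model.coefficients.to_csv(out_dir / "glmm_coefficients.tsv", sep="\t", index=False)
        results_summary["glmm"] = dict(
            zip(model.coefficients["term"], model.coefficients["estimate"])
        )

    # ---- provenance ----------------------------------------------------
    prov = {
        "config": _config_to_jsonable(config),
        "n_perm_effective": n_perm,
        "n_boot_effective": n_boot,
        "ci_profile": config.ci_profile,
        "versions": _versions(),
        "results": results_summary,
    }
    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return out_dir


def _config_to_jsonable(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _versions() -> dict:
    import mne
    import scipy

    from . import __version__

    return {
        "sospin": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "mne": mne.__version__,
    }


def make_fixtures(
    directory: str | Path,
    n_subjects: int = 3,
    duration_s: float = 60.0,
    seed: int = 0,
) -> tuple[Path, list[tuple[Recording, GroundTruth]]]:
    """Small on-disk cohort (EDF + sidecars + ground truth) for fast tests."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = GeneratorConfig(duration_s=duration_s, artifact_fraction=0.0)
    spec = CohortSpec(n_subjects=n_subjects, base=base, label="fixture")
    cohort, meta = synth.generate_cohort(spec, seed)
    meta.to_csv(directory / "cohort_metadata.tsv", sep="\t", index=False)
    entries = []
    for i, (rec, gt) in enumerate(cohort):
        name = f"fixture-{i:03d}"
        paths = io.write_recording(directory, rec, name=name)
        io.write_ground_truth(directory, gt, prefix=f"{name}_")
        entries.append(
            {
                "subject_id": name,
                "edf": paths["edf"].name,
                "hypnogram": paths["hypnogram"].name,
                "artifacts": paths["artifacts"].name,
            }
        )
    (directory / "manifest.yaml").write_text(yaml.safe_dump({"recordings": entries}))
    return directory, cohort
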