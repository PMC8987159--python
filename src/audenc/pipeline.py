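"""End-to-end orchestration: simulate -> train -> extract -> encode ->
group-stats -> compare, with a reproducibility manifest.

Every stage writes its artifacts under the run directory and registers
them (with SHA-256 checksums) in ``manifest.json`` alongside the exact
config and the per-stage seeds, so a run can be reproduced or audited
from the directory alone. Deterministic stages are bit-identical across
reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .baseline import WaveformClassifier, probe_layers
from .config import RunConfig
from .dcae import ConvAutoencoder, reconstruction_pcc
from .encoding import build_encoding_dataset, fit_sample, select_lambda
from .features import build_layer_designs
from .inference import (
    GroupZMap,
    normalize_map,
    one_sample_ttest,
    paired_ttest,
    threshold_map,
)
from .stimulus import segment_corpus, segment_excerpt
from .synthetic import generate_corpus, generate_voxels, sample_ground_truth

logger = aio.logger


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory handles to the run's main outputs."""

    out_dir: Path
    config: RunConfig
    manifest: dict
    zmaps: dict[str, dict[int, GroupZMap]]  # path ("unsupervised"/"supervised") -> layer -> map
    compare: dict[int, GroupZMap]  # unsupervised minus supervised, per layer
    truth: object = None
    reconstruction: tuple = None
    lambdas: dict = field(default_factory=dict)
    probe_report: pd.DataFrame = None
    dcae: object = None
    classifier: object = None
    designs: dict = field(default_factory=dict)  # path -> layer -> [per-excerpt D]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> PipelineResult:
    """Execute the full synthetic study and return its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = config.stimulus
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }
    config.to_yaml(out_dir / "config.yaml")

    def record(stage, files, seed=None, **extra):
        manifest["stages"][stage] = {
            "seed": seed,
            "files": {str(f.relative_to(out_dir)): _sha256(f) for f in files},
            **extra,
        }

    def run_stage(stage, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - halt with the stage name
            raise PipelineError(stage, exc) from exc
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
        return out

    # -- simulate audio ------------------------------------------------
    def _simulate():
        seed = config.stage_seed("simulate-audio")
        corpus = generate_corpus(spec, seed)
        manifest_path = aio.save_corpus(corpus, out_dir / "corpus")
        files = [manifest_path, *sorted((out_dir / "corpus").glob("*.wav"))]
        record("simulate-audio", files, seed=seed)
        return corpus

    corpus = run_stage("simulate-audio", _simulate)
    windows = segment_corpus(corpus.waveforms, spec)
    window_labels = np.repeat(corpus.labels, spec.windows_per_excerpt)

    # -- train the auto-encoder ---------------------------------------
    def _train_dcae():
        seed = config.stage_seed("train-dcae")
        model = ConvAutoencoder(
            filters=config.arch.filters,
            filter_lengths=config.arch.filter_lengths,
            pool_factors=config.arch.pool_factors,
            l2_weight=config.arch.l2_weight,
            learning_rate=config.training.learning_rate,
            beta_1=config.training.beta_1,
            beta_2=config.training.beta_2,
            epsilon=config.training.epsilon,
            weight_decay=config.training.weight_decay,
            batch_size=config.training.batch_size,
            max_epochs=config.training.max_epochs,
            tol=config.training.tol,
            patience=config.training.patience,
            random_state=seed,
        ).fit(windows)
        d = out_dir / "dcae"
        d.mkdir(exist_ok=True)
        loss_path = d / "loss.tsv"
        pd.DataFrame(
            {"epoch": np.arange(len(model.loss_curve_)), "loss": model.loss_curve_}
        ).to_csv(loss_path, sep="\t", index=False)
        np.savez_compressed(
            d / "weights.npz",
            **{f"enc_W{i}": w for i, w in enumerate(model.encoder_weights_)},
            **{f"enc_b{i}": b for i, b in enumerate(model.encoder_biases_)},
            **{f"dec_W{i}": w for i, w in enumerate(model.decoder_weights_)},
            **{f"dec_b{i}": b for i, b in enumerate(model.decoder_biases_)},
        )
        record("train-dcae", [loss_path, d / "weights.npz"], seed=seed,
               n_epochs=model.n_iter_, final_loss=model.loss_curve_[-1])
        return model

    dcae = run_stage("train-dcae", _train_dcae)
    recon = reconstruction_pcc(dcae, windows)

    # -- train the supervised classifier ------------------------------
    def _train_classifier():
        seed = config.stage_seed("train-classifier")
        clf = WaveformClassifier(
            filters=config.arch.filters,
            filter_lengths=config.arch.filter_lengths,
            pool_factors=config.arch.pool_factors,
            learning_rate=config.training.learning_rate,
            beta_1=config.training.beta_1,
            beta_2=config.training.beta_2,
            epsilon=config.training.epsilon,
            batch_size=config.training.batch_size,
            max_epochs=config.classifier.max_epochs,
            validation_fraction=config.classifier.validation_fraction,
            patience=config.classifier.patience,
            random_state=seed,
        )
        if config.classifier.warm_start_from_dcae:
            clf.initialize(spec.n_categories, random_state=seed)
            clf.set_encoder_weights(dcae.encoder_weights_, dcae.encoder_biases_)
            clf.warm_start = True
        clf.fit(windows, window_labels)
        d = out_dir / "classifier"
        d.mkdir(exist_ok=True)
        loss_path = d / "loss.tsv"
        pd.DataFrame(
            {
                "epoch": np.arange(len(clf.loss_curve_)),
                "train_loss": clf.loss_curve_,
                "val_loss": clf.validation_curve_,
            }
        ).to_csv(loss_path, sep="\t", index=False)
        record("train-classifier", [loss_path], seed=seed, n_epochs=clf.n_iter_)
        return clf

    clf = run_stage("train-classifier", _train_classifier)

    # -- extract hierarchical designs ----------------------------------
    def _extract():
        designs = {
            "unsupervised": build_layer_designs(dcae, corpus.waveforms, spec),
            "supervised": build_layer_designs(clf, corpus.waveforms, spec),
        }
        d = out_dir / "features"
        d.mkdir(exist_ok=True)
        files = []
        for path_name, per_layer in designs.items():
            for layer, mats in per_layer.items():
                f = d / f"{path_name}_layer{layer}.npz"
                np.savez_compressed(f, *mats)
                sidecar = f.with_suffix(".json")
                sidecar.write_text(
                    json.dumps(
                        {
                            "path": path_name,
                            "layer": layer,
                            "n_excerpts": len(mats),
                            "shape": list(mats[0].shape),
                            "hrf": "canonical double-gamma, TR grid",
                        }
                    )
                )
                files += [f, sidecar]
        record("extract-features", files)
        return designs

    designs = run_stage("extract-features", _extract)

    # -- simulate BOLD -------------------------------------------------
    def _simulate_bold():
        seed = config.stage_seed("simulate-bold")
        sim = config.simulation
        truth = sample_ground_truth(
            designs["unsupervised"],
            n_per_layer=sim.n_per_layer,
            n_null=sim.n_null,
            k=sim.k_nonzero,
            snr=sim.snr,
            seed=seed,
        )
        d = out_dir / "bold"
        d.mkdir(exist_ok=True)
        bold = {}
        files = []
        for s in range(spec.n_subjects):
            for e in range(spec.n_excerpts):
                pair_seed = config.stage_seed(f"simulate-bold/{s}/{e}")
                per_layer = {
                    layer: mats[e] for layer, mats in designs["unsupervised"].items()
                }
                X = generate_voxels(per_layer, truth, pair_seed)
                bold[(s, e)] = X
                f = d / f"sub{s:02d}_exc{e:03d}.nii.gz"
                aio.write_bold(f, X, spec.tr)
                files.append(f)
        mask_f = d / "truth_mask.nii.gz"
        aio.write_mask(mask_f, truth.layer_assignment)
        record("simulate-bold", files + [mask_f], seed=seed,
               n_voxels=truth.n_voxels, n_null=truth.n_null)
        return truth, bold

    truth, bold = run_stage("simulate-bold", _simulate_bold)

    # -- encoding ------------------------------------------------------
    def _encode():
        d = out_dir / "encode"
        d.mkdir(exist_ok=True)
        maps = {}
        lambdas = {}
        files = []
        summary_rows = []
        for path_name, per_layer in designs.items():
            maps[path_name] = {}
            for layer, mats in per_layer.items():
                samples = build_encoding_dataset(
                    mats, bold, spec, layer, categories=corpus.labels
                )
                if config.encoding.lam == "auto":
                    lam, rec = select_lambda(samples, config.encoding.lambda_grid)
                    rec.to_csv(
                        d / f"{path_name}_layer{layer}_lambda.tsv", sep="\t", index=False
                    )
                    files.append(d / f"{path_name}_layer{layer}_lambda.tsv")
                else:
                    lam = float(config.encoding.lam)
                lambdas[(path_name, layer)] = lam
                results = [fit_sample(s, lam) for s in samples]
                pccs = np.vstack([r.pcc for r in results])
                f = d / f"{path_name}_layer{layer}_pcc.npz"
                np.savez_compressed(
                    f,
                    pcc=pccs,
                    coef=np.stack([r.coef for r in results]),
                    lam=lam,
                    subjects=[r.subject for r in results],
                    excerpts=[r.excerpt for r in results],
                )
                files.append(f)
                maps[path_name][layer] = pccs
                for r in results:
                    summary_rows.append(
                        {
                            "path": path_name,
                            "layer": layer,
                            "subject": r.subject,
                            "excerpt": r.excerpt,
                            "mean_pcc": float(np.nanmean(r.pcc)),
                        }
                    )
        summary = d / "summary.tsv"
        pd.DataFrame(summary_rows).to_csv(summary, sep="\t", index=False)
        record("encode", files + [summary],
               lambdas={f"{p}/layer{l}": v for (p, l), v in lambdas.items()})
        return maps, lambdas

    pcc_maps, lambdas = run_stage("encode", _encode)

    # -- group statistics ---------------------------------------------
    def _group():
        d = out_dir / "groupmaps"
        d.mkdir(exist_ok=True)
        zmaps = {}
        files = []
        rows = []
        for path_name, per_layer in pcc_maps.items():
            zmaps[path_name] = {}
            for layer, pccs in per_layer.items():
                norm = np.vstack([normalize_map(row) for row in pccs])
                zm = one_sample_ttest(
                    norm, z_min=config.group.z_min, p_max=config.group.p_max
                )
                zmaps[path_name][layer] = zm
                _, count = threshold_map(zm, config.group.z_min, config.group.p_max)
                files += aio.write_zmap_volumes(d / f"{path_name}_layer{layer}", zm)
                rows.append(
                    {
                        "path": path_name,
                        "layer": layer,
                        "z_min": config.group.z_min,
                        "p_max": config.group.p_max,
                        "surviving_voxels": count,
                        "n_voxels": int(zm.z.size),
                    }
                )
        summary = d / "summary.tsv"
        pd.DataFrame(rows).to_csv(summary, sep="\t", index=False)
        record("group-stats", files + [summary])
        return zmaps

    zmaps = run_stage("group-stats", _group)

    # -- compare unsupervised vs supervised ----------------------------
    def _compare():
        d = out_dir / "compare"
        d.mkdir(exist_ok=True)
        compare = {}
        files = []
        rows = []
        for layer in pcc_maps["unsupervised"]:
            a = np.vstack(
                [normalize_map(r) for r in pcc_maps["unsupervised"][layer]]
            )
            b = np.vstack(
                [normalize_map(r) for r in pcc_maps["supervised"][layer]]
            )
            zm = paired_ttest(
                a, b, z_min=config.group.z_min, p_max=config.group.p_max
            )
            compare[layer] = zm
            _, count = threshold_map(zm, config.group.z_min, config.group.p_max)
            files += aio.write_zmap_volumes(d / f"unsup_minus_sup_layer{layer}", zm)
            rows.append({"layer": layer, "surviving_voxels": count})
        summary = d / "summary.tsv"
        pd.DataFrame(rows).to_csv(summary, sep="\t", index=False)
        record("compare", files + [summary])
        return compare

    compare = run_stage("compare", _compare)

    # -- layer probing report ------------------------------------------
    def _probe():
        feats = [m.mean(axis=1) for m in dcae.encode(windows)]
        report = probe_layers(
            feats, window_labels, folds=5, seed=config.stage_seed("probe-layers")
        )
        f = out_dir / "probe_layers.tsv"
        report.to_csv(f, sep="\t", index=False)
        record("probe-layers", [f])
        return report

    probe_report = run_stage("probe-layers", _probe)

    manifest["reconstruction_pcc_mean"] = recon[0]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        out_dir=out_dir,
        config=config,
        manifest=manifest,
        zmaps=zmaps,
        compare=compare,
        truth=truth,
        reconstruction=recon,
        lambdas=lambdas,
        probe_report=probe_report,
        dcae=dcae,
        classifier=clf,
        designs=designs,
    )
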