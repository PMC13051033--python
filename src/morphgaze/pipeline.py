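"""Pipeline driver: generate a synthetic world and run the three studies.

Study 1: Procrustes alignment, shape-on-score regression with permutation
significance, morph targets and composite images per trait.
Study 2: gaze parsing, condition fixation maps, pixel-wise morph contrasts,
and the rating mixed model.
Study 3: CNN scorer training and fine-tuning by rater sex, cross-validation,
Grad-CAM attention, significance masks, and fixation-vs-attention comparison.

Every artifact is listed in a manifest with a content hash; all seeds appear in
the manifest so deterministic stages reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import cnn, compare, gaze, impression, io as mgio, morphing, shape_core, synth

__all__ = ["RunConfig", "make_world", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, stage toggles and parameters for a full pipeline run."""

    world_dir: str
    out_dir: str
    seed: int = 0
    run_study1: bool = True
    run_study2: bool = True
    run_study3: bool = True
    # study 1
    n_perm: int = 1000
    morph_levels: tuple = impression.DEFAULT_MORPH_LEVELS
    # study 2
    smoothing_sigma_deg: float = 0.5
    px_per_deg: float = 35.0
    sampling_rate: float = 1000.0
    fdr_q: float = 0.05
    # study 3
    cnn_input: int = 64
    conv_filters: tuple = (16, 16, 32, 32, 64, 64)
    epochs: int = 20
    cv_folds: int = 5
    epsilon: float = 1e-8

    @property
    def smoothing_sigma_px(self) -> float:
        return self.smoothing_sigma_deg * self.px_per_deg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_world(
    config: synth.SyntheticWorldConfig,
    out_dir: str,
    n_participants: int | None = None,
    n_trials: int | None = None,
    write_gaze: bool = True,
) -> Path:
    """Emit a complete synthetic dataset directory plus its truth ledger.

    Sizes default to the config's design; pass smaller ``n_participants`` /
    ``n_trials`` for a quick world.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    template = synth.make_template()
    cfg = config
    if n_participants is not None:
        male = max(1, n_participants // 2)
        cfg = synth.SyntheticWorldConfig(
            **{
                **asdict(config),
                "n_participants_male": male,
                "n_participants_female": n_participants - male,
                **({"n_trials_per_participant": n_trials} if n_trials else {}),
            }
        )

    configs, scores, truth = synth.sample_population(cfg, template)
    mgio.write_landmark_configurations(
        configs, out / "landmarks_main.tps", out / "landmarks_semi.tps"
    )
    labels = [
        impression.ImpressionLabel(image_id=c.image_id, trait="dominance", score=float(s))
        for c, s in zip(configs, scores)
    ]
    mgio.write_labels_csv(out / "labels.csv", labels)
    for c in configs:
        img = synth.render_face(c, cfg.render_size, template)
        Image.fromarray(img.pixels).save(out / "images" / f"{c.image_id}.png")

    design = synth.make_design(cfg)
    rated, rating_truth = synth.simulate_ratings(design, cfg)
    rated.to_csv(out / "trials.csv", index=False)

    gaze_truth = []
    if write_gaze:
        (out / "gaze").mkdir(exist_ok=True)
        rng = np.random.default_rng(cfg.seed + 23)
        centers = {
            k: v.mean(axis=0) * cfg.render_size
            for k, v in synth.template_aoi_points(template).items()
        }
        for i in range(len(rated)):
            df, gt = synth.simulate_gaze(cfg, centers, (cfg.render_size, cfg.render_size), rng)
            df.to_csv(out / "gaze" / f"trial_{i:06d}.csv", index=False)
            gaze_truth.append(gt["n_fixations"])

    ledger = {
        "config": {k: v for k, v in asdict(cfg).items() if not isinstance(v, np.ndarray)},
        "population": {
            "beta_true": truth["beta_true"].tolist(),
            "scores": truth["scores"].tolist(),
            "noise_sd": truth["noise_sd"],
            "planned_variance_explained_pct": truth["planned_variance_explained_pct"],
        },
        "ratings": {
            k: (v if not isinstance(v, dict) else v)
            for k, v in rating_truth.items()
            if k not in ("participant_intercepts", "stimulus_intercepts")
        },
        "gaze_n_fixations": gaze_truth,
    }
    (out / "truth.json").write_text(json.dumps(ledger, indent=1))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled studies on a world directory; returns the manifest."""
    world = Path(config.world_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seeds": {"pipeline": config.seed}, "stages": {}, "artifacts": {}}
    t_all = time.time()
    template = synth.make_template()

    if not world.exists():
        raise FileNotFoundError(f"world directory {world} does not exist; run make-world first")

    configs = mgio.read_landmark_configurations(
        world / "landmarks_main.tps", world / "landmarks_semi.tps"
    )
    labels = mgio.read_labels_csv(world / "labels.csv")
    render_size = synth.SyntheticWorldConfig(**json.loads((world / "truth.json").read_text())["config"]).render_size if (world / "truth.json").exists() else 256

    aligned = model = None
    if config.run_study1:
        t0 = time.time()
        aligned = shape_core.gpa_align(configs)
        mgio.write_aligned_csv(out / "aligned.csv", aligned)
        model = impression.fit_shape_regression(aligned, labels)
        model.permutation_p = impression.permutation_test(
            aligned, labels, n_perm=config.n_perm, seed=config.seed
        )
        model.n_perm = config.n_perm
        model.to_json(out / "shape_model.json")
        # composite (average) faces at each morph level
        images = [
            morphing.FaceImage(
                pixels=np.asarray(Image.open(world / "images" / f"{c.image_id}.png")),
                image_id=c.image_id,
                landmarks=c,
            )
            for c in configs[: min(len(configs), 10)]
        ]
        for level in config.morph_levels:
            target = impression.predict_mean_morph(model, level)
            # map the aligned-frame morph into the first face's pixel frame for rendering
            ref = aligned.transforms[0].to_image(target.points_main)
            ref_cfg = shape_core.LandmarkConfiguration(
                points_main=ref,
                points_semi=shape_core.tps_transport(
                    configs[0].points_main, ref, configs[0].points_semi
                ),
                image_id=f"composite{level:+g}",
            )
            comp = morphing.average_faces(images, ref_cfg)
            Image.fromarray(comp.pixels).save(out / f"composite_{level:+g}sd.png")
        manifest["stages"]["study1"] = {
            "variance_explained_pct": model.variance_explained_pct,
            "permutation_p": model.permutation_p,
            "elapsed_s": round(time.time() - t0, 2),
        }

    if config.run_study2:
        t0 = time.time()
        rated = pd.read_csv(world / "trials.csv")
        settings = gaze.EventParserSettings(
            sampling_rate=config.sampling_rate, px_per_deg=config.px_per_deg
        )
        fixations_by_row = []
        gaze_dir = world / "gaze"
        n_gaze = len(list(gaze_dir.glob("trial_*.csv"))) if gaze_dir.exists() else 0
        for i in range(len(rated)):
            path = gaze_dir / f"trial_{i:06d}.csv"
            if i >= n_gaze or not path.exists():
                fixations_by_row.append([])
                continue
            df = pd.read_csv(path)
            fx, _, _, _ = gaze.parse_events(
                df.t_ms, df.x_px.fillna(0.0), df.y_px.fillna(0.0), df.valid, settings
            )
            fixations_by_row.append(fx)
        trials = synth.trials_from_design(rated, fixations_by_row)
        shape = (render_size, render_size)
        fmap = gaze.fixation_map(trials, shape, config.smoothing_sigma_px)
        np.save(out / "fixation_map.npy", fmap.grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                contrast = gaze.pixelwise_contrast(
                    trials, shape, config.smoothing_sigma_px, q=config.fdr_q
                )
                np.save(out / "contrast_beta.npy", contrast.beta)
                np.save(out / "contrast_mask.npy", contrast.sig_mask)
                n_sig = int(contrast.sig_mask.sum())
            except ValueError:
                n_sig = None
        lmm = gaze.fit_rating_lmm(rated[rated.trait == rated.trait.iloc[0]])
        (out / "rating_lmm.json").write_text(
            json.dumps(
                {
                    "fixed_effects": lmm.fixed_effects,
                    "random_intercept_sd": lmm.random_intercept_sd,
                    "residual_sd": lmm.residual_sd,
                    "singular": lmm.singular,
                },
                indent=1,
            )
        )
        manifest["stages"]["study2"] = {
            "n_trials": len(trials),
            "n_sig_pixels": n_sig,
            "lmm_morph_estimate": lmm.estimate("morph"),
            "elapsed_s": round(time.time() - t0, 2),
        }

    if config.run_study3:
        t0 = time.time()
        size = config.cnn_input
        imgs = np.stack(
            [synth.render_face(c, size, template).pixels for c in configs]
        )
        score_by_id = {l.image_id: l.score for l in labels}
        y = np.array([score_by_id[c.image_id] for c in configs])
        yz = (y - y.mean()) / y.std()
        ccfg = cnn.CnnConfig(
            input_size=(size, size, 3),
            conv_filters=config.conv_filters,
            epochs=config.epochs,
            seed=config.seed,
        )
        base = cnn.build_scorer(ccfg)
        cnn.train(base, imgs, yz)
        cv = cnn.cross_validate(imgs, yz, ccfg, k=config.cv_folds, epochs=max(2, config.epochs // 4))
        pd.DataFrame({"fold": range(1, config.cv_folds + 1), "r": cv.fold_r, "p": cv.fold_p}).to_csv(
            out / "cv_report.csv", index=False
        )
        maps = [cnn.gradcam(base, im).grid for im in imgs]
        mean_map = np.mean(maps, axis=0)
        np.save(out / "gradcam_mean.npy", mean_map)
        sig = cnn.attention_significance(maps[: min(len(maps), 50)], q=config.fdr_q)
        np.save(out / "gradcam_sig.npy", sig)

        # fixation-vs-attention comparison on matched raster
        comp_row = {}
        fmap_path = out / "fixation_map.npy"
        if fmap_path.exists():
            fgrid = np.load(fmap_path)
            from skimage.transform import resize

            fsmall = resize(fgrid, (size, size), order=1, anti_aliasing=True)
            if fsmall.sum() > 0:
                aois = compare.aois_from_points(
                    {k: v * size for k, v in synth.template_aoi_points(template).items()},
                    (size, size),
                    dilate_radius=max(2, size // 32),
                )
                res = compare.compare_maps(fsmall, mean_map, aois, epsilon=config.epsilon)
                comp_row = {
                    "kld_fix_vs_att": res.kld_fix_vs_att,
                    "kld_att_vs_fix": res.kld_att_vs_fix,
                    "kld_symmetric": res.kld_symmetric,
                    "aoi_r": res.aoi_r,
                    "aoi_p": res.aoi_p,
                }
                pd.DataFrame([comp_row]).to_csv(out / "comparison.csv", index=False)
        manifest["stages"]["study3"] = {
            "cv_mean_r": cv.mean_r,
            "final_train_mse": base.history[-1],
            **comp_row,
            "elapsed_s": round(time.time() - t0, 2),
        }

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
    manifest["elapsed_s"] = round(time.time() - t_all, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
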