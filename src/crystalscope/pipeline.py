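"""End-to-end orchestration: run configs, fixtures, study simulation and the
reproducibility manifest.

A run is described by a JSON-serializable :class:`RunConfig` (validated with
pydantic); ``run_pipeline`` executes the requested stages in dependency
order, writes every artifact under the output directory and finishes with a
manifest recording the config echo, per-stage outputs with SHA-256
checksums, wall-clock times and warnings. One top-level seed drives all
stochastic stages through independently spawned substreams, so reruns with
the same config reproduce every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Any, Literal

import numpy as np
from pydantic import BaseModel, Field

from . import io as cio
from . import morphometry as cmorph
from . import spectra as cspec
from . import stats as cstats
from . import synth as csynth

__all__ = [
    "MorphometrySettings",
    "SpectralSettings",
    "StudySettings",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
    "make_fixtures",
    "simulate_study",
]


class MorphometrySettings(BaseModel):
    overlap_fraction_max: float = 0.2
    min_object_px: int = 8
    h_maxima: float = 1.0
    smooth_sigma_px: float = 1.0
    split_crossings: bool = True
    needle_halfband_px: float = 2.0
    axis_residual_p90_max: float = 2.4
    rect_fill_single_min: float = 0.72
    length_metric: Literal["feret", "skeleton"] = "feret"

    def to_config(self) -> cmorph.MorphometryConfig:
        return cmorph.MorphometryConfig(**self.model_dump())


class SpectralSettings(BaseModel):
    ce_fraction_min: float = 0.5
    residual_max: float = 0.1
    unsaturation_center_cm1: float = 3010.0
    unsaturation_half_width_cm1: float = 20.0
    ester_center_cm1: float = 1740.0
    ester_half_width_cm1: float = 20.0
    min_prominence: float = 0.12

    def to_config(self) -> cspec.CompositionConfig:
        return cspec.CompositionConfig(
            ce_fraction_min=self.ce_fraction_min,
            residual_max=self.residual_max,
            unsaturation_window=cspec.BandWindow(
                self.unsaturation_center_cm1,
                self.unsaturation_half_width_cm1,
                self.min_prominence,
            ),
            ester_window=cspec.BandWindow(
                self.ester_center_cm1, self.ester_half_width_cm1, self.min_prominence
            ),
        )


class StudySettings(BaseModel):
    """Paper-analog two-group design: a few animals per group, a few SHG
    fields per animal, with group differences injected through the needle
    length and density of the generator."""

    n_control_animals: int = 2
    n_infected_animals: int = 3
    images_per_animal: tuple[int, ...] = (3, 4)
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    control_mean_needles: float = 24.0
    control_mean_length_um: float = 15.0
    length_gamma_shape: float = 6.0
    infected_length_factor: float = 0.67
    infected_density_factor: float = 1.5
    width_px: float = 3.0
    noise_sd: float = 10.0
    metric: str = "mean_length_um"
    method: str = "MANN_WHITNEY_U"
    aggregate_by_animal: bool = False


class RunConfig(BaseModel):
    """Validated top-level configuration of a pipeline run."""

    seed: int = 0
    output_dir: str = "crystalscope_out"
    pixel_size_um: float = 0.5
    # stage inputs: either paths to data on disk, or synthetic scene requests
    morphometry_image: str | None = None
    synth_needle_field: dict[str, Any] | None = None
    cube_path: str | None = None
    cube_sidecar: str | None = None
    synth_cube_classes: list[str] | None = None
    rois: list[dict[str, Any]] | None = None
    reflectance_image: str | None = None
    plaque_mask: str | None = None
    synth_reflectance: dict[str, Any] | None = None
    study: StudySettings | None = None
    morphometry: MorphometrySettings = Field(default_factory=MorphometrySettings)
    spectral: SpectralSettings = Field(default_factory=SpectralSettings)


class RunManifest(BaseModel):
    config: dict
    software_version: str
    stages: list[dict]
    warnings: list[str]

    def write(self, path: Path) -> None:
        path.write_text(self.model_dump_json(indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages and write artifacts plus a manifest.

    Stages run in dependency order: synthesis (if requested), morphometry,
    spectral calls, burden. Any stage error aborts the run with the stage
    name and the offending input path.
    """
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    caught: list[str] = []
    seeds = _spawn_seeds(config.seed, 4)
    mcfg = config.morphometry.to_config()
    scfg = config.spectral.to_config()

    def record(name: str, t0: float, outputs: list[Path], extra: dict | None = None) -> None:
        stages.append(
            {
                "stage": name,
                "wall_s": round(time.perf_counter() - t0, 4),
                "outputs": {str(p): _sha256(p) for p in outputs},
                **(extra or {}),
            }
        )

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- morphometry ---------------------------------------------------
        image = None
        if config.synth_needle_field is not None:
            t0 = time.perf_counter()
            params = csynth.NeedleFieldParams(
                **{"seed": seeds[0], "pixel_size_um": config.pixel_size_um,
                   **config.synth_needle_field}
            )
            image, gt = csynth.generate_needle_field(params)
            img_path = out / "needle_field.tif"
            gt_path = out / "needle_field_truth.json"
            cio.write_image(img_path, image)
            gt_path.write_text(json.dumps(gt.to_dict()))
            record("synth_needle_field", t0, [img_path, gt_path])
        elif config.morphometry_image is not None:
            p = Path(config.morphometry_image)
            if not p.exists():
                raise FileNotFoundError(f"stage morphometry: missing input {p}")
            image = cio.read_image(p, config.pixel_size_um, cio.ChannelLabel.SHG)

        if image is not None:
            t0 = time.perf_counter()
            result = cmorph.run_morphometry(image, mcfg)
            res_path = out / "morphometry.json"
            res_path.write_text(json.dumps(result.to_dict(), indent=2))
            csv_path = out / "objects.csv"
            _write_object_table(csv_path, result)
            passed_path = out / "labels_passed.tif"
            failed_path = out / "labels_failed.tif"
            _write_status_masks(passed_path, failed_path, result, image.shape)
            record(
                "morphometry",
                t0,
                [res_path, csv_path, passed_path, failed_path],
                {"n_total": result.n_total, "n_passed": result.n_passed},
            )

        # --- spectra -------------------------------------------------------
        cube = None
        if config.synth_cube_classes is not None:
            t0 = time.perf_counter()
            classes = [csynth.SceneClass(c) for c in config.synth_cube_classes]
            n = len(classes)
            side = 8
            cmap = np.empty((side, side * n), dtype=object)
            for k, cls in enumerate(classes):
                cmap[:, k * side : (k + 1) * side] = cls.value
            scene = csynth.SpectralScene(class_map=cmap, noise_sd=0.05, seed=seeds[1])
            cube, _ = csynth.generate_cube(
                scene, csynth.CH_STRETCH_AXIS, pixel_size_um=config.pixel_size_um
            )
            cube_path = out / "cube.tif"
            sidecar = out / "cube.json"
            cio.write_cube(cube_path, sidecar, cube)
            record("synth_cube", t0, [cube_path, sidecar])
            if config.rois is None:
                config = config.model_copy(
                    update={
                        "rois": [
                            {
                                "shape": "DISK",
                                "center": [side / 2, k * side + side / 2],
                                "radius": side / 3,
                                "name": cls.value,
                            }
                            for k, cls in enumerate(classes)
                        ]
                    }
                )
        elif config.cube_path is not None:
            p = Path(config.cube_path)
            if not p.exists():
                raise FileNotFoundError(f"stage spectra: missing input {p}")
            cube = cio.read_cube(p, config.cube_sidecar)

        if cube is not None and config.rois:
            t0 = time.perf_counter()
            library = cspec.ReferenceLibrary.from_band_model(cube.axis)
            rows = []
            for roi_dict in config.rois:
                roi = cio.Roi.from_dict(roi_dict)
                spec = cspec.extract_roi_spectrum(cube, roi)
                call = cspec.classify_composition(spec, library, scfg)
                rows.append((roi.name, call))
            calls_path = out / "composition_calls.csv"
            _write_calls_table(calls_path, rows)
            record("spectra", t0, [calls_path], {"n_rois": len(rows)})

        # --- burden --------------------------------------------------------
        if config.synth_reflectance is not None:
            t0 = time.perf_counter()
            kwargs = dict(config.synth_reflectance)
            shape = tuple(kwargs.pop("shape", (256, 256)))
            ellipse = tuple(kwargs.pop("plaque_ellipse", (128, 128, 90, 110)))
            frac = kwargs.pop("crystal_fraction", 0.1)
            refl, plaque, _ = csynth.generate_reflectance_section(
                shape, ellipse, frac, seed=seeds[2], **kwargs
            )
            burden = cstats.compute_burden(refl, plaque)
            b_path = out / "burden.json"
            b_path.write_text(json.dumps(burden.to_dict(), indent=2))
            record("burden", t0, [b_path], {"burden_percent": burden.burden_percent})
        elif config.reflectance_image is not None:
            t0 = time.perf_counter()
            p = Path(config.reflectance_image)
            if not p.exists():
                raise FileNotFoundError(f"stage burden: missing input {p}")
            refl = cio.read_image(p, config.pixel_size_um, cio.ChannelLabel.REFLECTANCE)
            if config.plaque_mask is None:
                raise ValueError("stage burden: plaque_mask is required with a reflectance image")
            pm = cio.read_image(config.plaque_mask, config.pixel_size_um).pixels > 0
            burden = cstats.compute_burden(refl, pm)
            b_path = out / "burden.json"
            b_path.write_text(json.dumps(burden.to_dict(), indent=2))
            record("burden", t0, [b_path], {"burden_percent": burden.burden_percent})

        # --- study ---------------------------------------------------------
        if config.study is not None:
            t0 = time.perf_counter()
            comparison = simulate_study(config.study, seed=seeds[3], morph_config=mcfg)
            s_path = out / "study_comparison.json"
            s_path.write_text(json.dumps(comparison.to_dict(), indent=2))
            record("study", t0, [s_path], {"p_value": comparison.p_value})

        caught = [str(w.message) for w in wrec]

    manifest = RunManifest(
        config=json.loads(config.model_dump_json()),
        software_version=__version__,
        stages=stages,
        warnings=caught,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _write_object_table(path: Path, result: cmorph.MorphometryResult) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "pixel_count", "length_um", "orientation_deg", "status", "overlap_fraction"])
        for o in result.objects:
            w.writerow(
                [o.label, o.pixel_count, f"{o.length_um:.4f}", f"{o.orientation_deg:.2f}",
                 o.status.value, f"{o.overlap_fraction:.4f}"]
            )


def _write_status_masks(
    passed_path: Path, failed_path: Path, result: cmorph.MorphometryResult, shape: tuple[int, int]
) -> None:
    passed = np.zeros(shape, dtype=np.uint16)
    failed = np.zeros(shape, dtype=np.uint16)
    for o in result.objects:
        target = passed if o.status is cmorph.ObjectStatus.PASSED else failed
        target[o.pixels[:, 0], o.pixels[:, 1]] = o.label
    cio.write_image(passed_path, passed, dtype=np.uint16)
    cio.write_image(failed_path, failed, dtype=np.uint16)


def _write_calls_table(path: Path, rows) -> None:
    import csv

    species = list(csynth.Species)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["roi"]
            + [f"fraction_{sp.value}" for sp in species]
            + ["residual_rms", "unsaturation_band", "ester_band", "dominant_class"]
        )
        for name, call in rows:
            w.writerow(
                [name]
                + [f"{call.fractions.get(sp, 0.0):.4f}" for sp in species]
                + [
                    f"{call.residual_rms:.5f}",
                    call.unsaturation_band_present,
                    call.ester_band_present,
                    call.dominant_class.value,
                ]
            )


# ---------------------------------------------------------------------------
# Study simulation (two-group paper-analog design)
# ---------------------------------------------------------------------------

def _study_group_results(
    settings: StudySettings,
    rng: np.random.Generator,
    infected: bool,
    morph_config: cmorph.MorphometryConfig,
) -> tuple[list[cmorph.MorphometryResult], list[int]]:
    n_animals = settings.n_infected_animals if infected else settings.n_control_animals
    mean_needles = settings.control_mean_needles * (
        settings.infected_density_factor if infected else 1.0
    )
    mean_length = settings.control_mean_length_um * (
        settings.infected_length_factor if infected else 1.0
    )
    shape_k = settings.length_gamma_shape
    results = []
    animal_ids = []
    for animal in range(n_animals):
        n_images = settings.images_per_animal[animal % len(settings.images_per_animal)]
        for _ in range(n_images):
            n_needles = max(1, int(rng.poisson(mean_needles)))
            params = csynth.NeedleFieldParams(
                image_shape=settings.image_shape,
                pixel_size_um=settings.pixel_size_um,
                n_needles=n_needles,
                length_family=csynth.LengthDistribution.GAMMA,
                length_params=(shape_k, mean_length / shape_k),
                width_px=settings.width_px,
                noise_sd=settings.noise_sd,
                min_length_um=4.0,
                max_length_um=min(settings.image_shape) * settings.pixel_size_um / 3.0,
                seed=int(rng.integers(2**31)),
            )
            image, _ = csynth.generate_needle_field(params)
            results.append(cmorph.run_morphometry(image, morph_config))
            animal_ids.append(animal)
    return results, animal_ids


def simulate_study(
    settings: StudySettings | None = None,
    seed: int = 0,
    null: bool = False,
    morph_config: cmorph.MorphometryConfig | None = None,
) -> cstats.GroupComparison:
    """Simulate one two-group imaging study and compare the groups.

    Control and infected-like groups are rendered with the generator (the
    infected group has shorter, denser needles unless ``null`` is set, in
    which case both groups share the control parameters), each image is
    processed by the full morphometry pipeline, and the configured
    per-image metric is compared between groups.
    """
    settings = settings or StudySettings()
    morph_config = morph_config or cmorph.MorphometryConfig()
    rng = np.random.default_rng(seed)
    control, control_ids = _study_group_results(settings, rng, infected=False, morph_config=morph_config)
    if null:
        null_settings = settings.model_copy(
            update={"infected_length_factor": 1.0, "infected_density_factor": 1.0}
        )
        infected, infected_ids = _study_group_results(
            null_settings, rng, infected=True, morph_config=morph_config
        )
    else:
        infected, infected_ids = _study_group_results(
            settings, rng, infected=True, morph_config=morph_config
        )
    groups = {"control": control, "infected": infected}
    ids = (
        {"control": control_ids, "infected": infected_ids}
        if settings.aggregate_by_animal
        else None
    )
    return cstats.compare_study(groups, settings.metric, settings.method, animal_ids=ids)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixtures(output_dir: str | Path, seed: int = 0) -> list[Path]:
    """Materialize the standard test scenes with ground truth beside each.

    Writes: a disjoint needle field, a field with forced crossings, pure and
    mixed hyperspectral cubes on the CH-stretch axis, reference spectra on
    both axes, and a reflectance section — every artifact loadable through
    the I/O layer.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(seed, 4)
    paths: list[Path] = []

    def emit_field(name: str, params: csynth.NeedleFieldParams) -> None:
        image, gt = csynth.generate_needle_field(params)
        p_img = out / f"{name}.tif"
        p_gt = out / f"{name}_truth.json"
        cio.write_image(p_img, image)
        p_gt.write_text(json.dumps(gt.to_dict()))
        paths.extend([p_img, p_gt])

    emit_field("needles_disjoint", csynth.NeedleFieldParams(seed=seeds[0]))
    emit_field(
        "needles_crossing",
        csynth.NeedleFieldParams(seed=seeds[0], n_forced_crossing_pairs=3),
    )

    # hyperspectral scene: one stripe per class
    classes = [
        csynth.SceneClass.PROTEIN,
        csynth.SceneClass.AMORPHOUS_LIPID,
        csynth.SceneClass.CE_CRYSTAL_LINOLEATE,
        csynth.SceneClass.FC_CRYSTAL,
    ]
    side = 8
    cmap = np.empty((side, side * len(classes)), dtype=object)
    for k, cls in enumerate(classes):
        cmap[:, k * side : (k + 1) * side] = cls.value
    scene = csynth.SpectralScene(class_map=cmap, noise_sd=0.05, seed=seeds[1])
    cube, _ = csynth.generate_cube(scene, csynth.CH_STRETCH_AXIS)
    p_cube, p_side = out / "cube_classes.tif", out / "cube_classes.json"
    cio.write_cube(p_cube, p_side, cube)
    truth = {"classes": [c.value for c in classes], "stripe_px": side, "noise_sd": 0.05}
    p_truth = out / "cube_classes_truth.json"
    p_truth.write_text(json.dumps(truth))
    paths.extend([p_cube, p_side, p_truth])

    for axis, tag in ((csynth.CH_STRETCH_AXIS, "ch"), (csynth.FINGERPRINT_AXIS, "fp")):
        for sp in csynth.Species:
            spec = csynth.synth_reference_spectrum(sp, axis)
            p_csv = out / f"ref_{tag}_{sp.value}.csv"
            cio.write_spectrum(p_csv, spec)
            paths.append(p_csv)

    refl, plaque, crystal = csynth.generate_reflectance_section(
        (256, 256), (128, 128, 90, 110), 0.10, seed=seeds[2]
    )
    p_refl = out / "reflectance.tif"
    cio.write_image(p_refl, refl)
    p_pm = out / "reflectance_plaque_mask.tif"
    cio.write_image(p_pm, plaque.astype(np.uint8), dtype=np.uint8)
    p_cm = out / "reflectance_crystal_mask.tif"
    cio.write_image(p_cm, crystal.astype(np.uint8), dtype=np.uint8)
    paths.extend([p_refl, p_pm, p_cm])
    return paths
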