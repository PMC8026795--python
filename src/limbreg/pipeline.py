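"""End-to-end pipeline: register femur and tibia, transform the 3D models
into the standing pose, measure alignment in both states, write a report.

Inputs are the clinical artifacts: a CT volume, the biplanar radiographs with
their calibration, per-segment STL meshes, arrow/mask annotations (JSON) and
measurement landmarks (JSON). Outputs are the two 4x4 transforms and a JSON
report with weight-bearing and non-weight-bearing MA/JLCA and their absolute
differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .drr import CTVolume, RadiographPair, hu_to_attenuation
from .geometry import EOSGeometry
from .measurements import BoneMesh, measure_alignment
from .registration import ArrowAnnotation, ROIMask, RegistrationConfig, register_bone
from .transforms import RigidTransform

__all__ = ["PipelineConfig", "run_pipeline", "transform_mesh", "load_annotations"]

log = logging.getLogger("limbreg")

#: which bone's registration transform carries each landmark group
LANDMARK_OWNER = {
    "femoral_head_points": "femur",
    "epicondyles": "femur",
    "patella_points": "femur",
    "eminences": "tibia",
    "plateau_points": "tibia",
}
#: which bone's transform carries each mesh segment
SEGMENT_OWNER = {"femur": "femur", "patella": "femur",
                 "tibia": "tibia", "fibula": "tibia", "talus": "tibia"}


@dataclass
class PipelineConfig:
    """Paths and options of a full pipeline run (round-trips through YAML)."""

    ct_path: str
    frontal_path: str
    lateral_path: str
    geometry_path: str
    mesh_dir: str
    annotations_path: str
    landmarks_path: str
    output_dir: str
    side: str = "right"
    ajc_threshold: float = 3.0
    epicondyle_cut_fraction: float = 0.15
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        reg = d.pop("registration", None)
        cfg = cls(**d)
        if reg:
            cfg.registration = RegistrationConfig(**reg)
        return cfg


def transform_mesh(mesh: BoneMesh, t: RigidTransform) -> BoneMesh:
    """Apply a rigid transform to every vertex; topology unchanged."""
    return mesh.transformed(t)


def load_annotations(path) -> dict:
    """Read the annotation JSON: per-bone arrows and rectangular masks.

    Schema: ``{<bone>: {"arrows": {"frontal": [[h,v],[h,v]], "lateral": ...,
    "ct": [[x,y,z],[x,y,z]]}, "masks": {"frontal": [r0,c0,r1,c1],
    "lateral": [...]}}}`` or the flat variant produced by the simulator.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "arrows" in raw:  # simulator layout: arrows/masks keyed by bone inside
        out = {}
        for bone in raw["arrows"]:
            out[bone] = {"arrows": raw["arrows"][bone], "masks": raw["masks"][bone]}
        return out
    return raw


def _load_image(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(str(path)), dtype=float)


def _measure_state(meshes, landmarks, cfg: PipelineConfig):
    return measure_alignment(
        meshes, landmarks, side=cfg.side,
        ajc_threshold=cfg.ajc_threshold,
        epicondyle_cut_fraction=cfg.epicondyle_cut_fraction,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run register -> transform -> measure -> report and return the report.

    Angles in the report are rounded to 0.1 deg (distances to 0.1 mm) in the
    human-readable fields; full precision is kept in the ``*_raw`` machine
    fields. Stage failures raise with a stage-prefixed message; outputs
    written before the failure are retained in ``output_dir``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[stage {name}] {exc}") from exc

    for name, p in (("ct", cfg.ct_path), ("frontal image", cfg.frontal_path),
                    ("lateral image", cfg.lateral_path), ("geometry", cfg.geometry_path),
                    ("annotations", cfg.annotations_path), ("landmarks", cfg.landmarks_path)):
        if not Path(p).exists():
            raise FileNotFoundError(f"[stage inputs] missing {name} file: {p}")

    geom = _stage("inputs", EOSGeometry.from_yaml, cfg.geometry_path)
    volume = _stage("inputs", CTVolume.from_file, cfg.ct_path)
    pair = RadiographPair(
        frontal=_load_image(cfg.frontal_path),
        lateral=_load_image(cfg.lateral_path),
        geometry=geom,
    )
    annotations = _stage("inputs", load_annotations, cfg.annotations_path)
    with open(cfg.landmarks_path) as fh:
        landmarks = {k: np.asarray(v, dtype=float) for k, v in json.load(fh).items()}
    meshes = {}
    for stl in sorted(Path(cfg.mesh_dir).glob("*.stl")):
        meshes[stl.stem] = BoneMesh.from_stl(stl, label=stl.stem)
    log.info("loaded %d meshes, volume %s", len(meshes), volume.shape)

    mu = hu_to_attenuation(volume)
    transforms: dict[str, RigidTransform] = {}
    registration_info = {}
    for bone in ("femur", "tibia"):
        ann = annotations[bone]
        arrow = ArrowAnnotation.from_dict(ann["arrows"])
        masks = tuple(ROIMask(*ann["masks"][p]) for p in ("frontal", "lateral"))
        result = _stage(f"register:{bone}", register_bone, mu, pair, arrow, masks,
                        cfg.registration)
        transforms[bone] = result.transform
        registration_info[bone] = {
            "cost": result.cost,
            "n_evaluations": result.n_evaluations,
            "converged": result.converged,
            "message": result.message,
        }
        with open(out_dir / f"transform_{bone}.json", "w") as fh:
            json.dump({"frame": "CT->EOS", "matrix": result.transform.matrix.tolist()}, fh, indent=1)
        (out_dir / f"transform_{bone}.txt").write_text(
            "# rigid transform, CT frame -> EOS world frame\n" + result.transform.to_text()
        )
        log.info("registered %s: cost=%.4f evals=%d", bone, result.cost, result.n_evaluations)

    wb_meshes = {name: transform_mesh(m, transforms[SEGMENT_OWNER.get(name, "tibia")])
                 for name, m in meshes.items()}
    wb_landmarks = {name: transforms[LANDMARK_OWNER.get(name, "tibia")].apply(pts)
                    for name, pts in landmarks.items()}

    nwb = _stage("measure:nwb", _measure_state, meshes, landmarks, cfg)
    wb = _stage("measure:wb", _measure_state, wb_meshes, wb_landmarks, cfg)

    report = {
        "side": cfg.side,
        "non_weight_bearing": {"MA_deg": round(nwb.ma, 1), "JLCA_deg": round(nwb.jlca, 1)},
        "weight_bearing": {"MA_deg": round(wb.ma, 1), "JLCA_deg": round(wb.jlca, 1)},
        "difference_abs": {
            "MA_deg": round(abs(wb.ma - nwb.ma), 1),
            "JLCA_deg": round(abs(wb.jlca - nwb.jlca), 1),
        },
        "raw": {
            "MA_nwb": nwb.ma, "JLCA_nwb": nwb.jlca,
            "MA_wb": wb.ma, "JLCA_wb": wb.jlca,
        },
        "registration": registration_info,
        "ajc_point_count": {"nwb": nwb.ajc_point_count, "wb": wb.ajc_point_count},
        "seed": cfg.seed,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
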