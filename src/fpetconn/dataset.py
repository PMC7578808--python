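"""BIDS-like dataset discovery and pipeline configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class SubjectPaths:
    subject_id: str
    pet: Path | None = None
    pet_sidecar: Path | None = None
    func: Path | None = None
    blood: Path | None = None
    motion_par: Path | None = None

    @property
    def has_pet(self) -> bool:
        return self.pet is not None

    @property
    def has_func(self) -> bool:
        return self.func is not None


@dataclass
class DatasetLayout:
    """Resolved file layout of a study directory (sub-*/pet, sub-*/func, ...)."""

    root: Path
    subjects: list[SubjectPaths]
    parcellation: Path | None = None
    participants: Path | None = None

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def discover_dataset(root: str | Path) -> DatasetLayout:
    """Enumerate subjects and modality files under a BIDS-like root.

    Missing optional modalities are logged, not fatal; a root with no sub-*
    folders is rejected.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    sub_dirs = sorted(d for d in root.glob("sub-*") if d.is_dir())
    if not sub_dirs:
        raise ValueError(f"no sub-* folders under {root}")
    subjects = []
    for d in sub_dirs:
        sid = d.name
        sp = SubjectPaths(subject_id=sid)
        pets = sorted((d / "pet").glob(f"{sid}*_pet.nii.gz")) if (d / "pet").is_dir() else []
        if pets:
            sp.pet = pets[0]
            sidecar = sp.pet.with_name(sp.pet.name.replace(".nii.gz", ".json"))
            sp.pet_sidecar = sidecar if sidecar.exists() else None
        else:
            logger.warning("%s: no PET image found", sid)
        funcs = sorted((d / "func").glob(f"{sid}*_bold.nii.gz")) if (d / "func").is_dir() else []
        if funcs:
            sp.func = funcs[0]
        else:
            logger.warning("%s: no BOLD image found", sid)
        bloods = sorted((d / "pet").glob(f"{sid}*blood*.tsv")) if (d / "pet").is_dir() else []
        if bloods:
            sp.blood = bloods[0]
        pars = sorted((root / "derivatives" / "mcflirt" / sid).rglob("*.par"))
        if pars:
            sp.motion_par = pars[0]
        subjects.append(sp)
    parc_candidates = sorted((root / "derivatives" / "parcellation").glob("*.nii.gz"))
    participants = root / "participants.tsv"
    return DatasetLayout(
        root=root,
        subjects=subjects,
        parcellation=parc_candidates[0] if parc_candidates else None,
        participants=participants if participants.exists() else None,
    )


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis, serializable to YAML."""

    # acquisition / window
    scan_duration_s: float = 5700.0
    frame_duration_s: float = 16.0
    analysis_onset_s: float = 1800.0
    n_blocks: int = 6
    block_duration_s: float = 600.0
    # gradient filter
    sigma_spatial_vox: float = 1.0
    sigma_temporal_frames: float = 2.0
    window_extent: int = 7
    edge_policy: str = "valid"
    # connectivity
    fisher_z_average: bool = True
    run_block_stability: bool = True
    # fMRI
    fmri_highpass_hz: float = 0.01
    fmri_tr_s: float = 2.45
    # plasma
    half_life_s: float = 6586.2
    # execution
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_extent < 3 or self.window_extent % 2 == 0:
            raise ValueError("window_extent must be odd and >= 3")
        if self.edge_policy not in ("valid", "renormalized"):
            raise ValueError("edge_policy must be 'valid' or 'renormalized'")
        if min(self.sigma_spatial_vox, self.sigma_temporal_frames) <= 0:
            raise ValueError("filter widths must be positive")
        if self.frame_duration_s <= 0 or self.scan_duration_s <= 0:
            raise ValueError("durations must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
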