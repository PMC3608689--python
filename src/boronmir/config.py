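"""Pipeline configuration: every threshold the stages use, in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """Thresholds for the full pipeline, with the published defaults."""

    mfei_threshold: float = 0.67
    max_mature_mismatch: int = 3
    max_star_mismatch: int = 6
    min_lp: int = 60
    fold_threshold: float = 2.0
    target_penalty: float = 3.0
    degradome_window: int = 1
    homology_k: int = 11
    min_identity: float = 85.0
    evalue_max: float = 1e-10
    flank: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"config value {f.name} must be positive")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = int(val) if types[key] == "int" else float(val)
        return cls(**kwargs)
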