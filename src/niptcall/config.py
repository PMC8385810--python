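"""Run configuration: decision thresholds and pipeline parameters."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Thresholds and sizes shared by all pipeline stages.

    Defaults encode the screening decision rule: a chromosome is reported
    positive when its z-score exceeds ``z_positive_cutoff`` with fetal
    fraction at least ``ff_min``; calls with z below ``z_gray_upper`` are
    flagged as gray-zone positives (enriched for false positives).
    Subchromosomal segments require a combined (Stouffer) |Z| above
    ``cnv_z_cutoff``.
    """

    bin_size: int = 1_000_000
    loess_span: float = 0.3
    z_positive_cutoff: float = 3.0
    z_gray_upper: float = 5.0
    ff_min: float = 0.04
    cnv_z_cutoff: float = 5.0
    cnv_seed_z: float = 2.0
    cnv_min_windows: int = 2
    min_panel_size: int = 30
    gc_band_low: float = 0.30
    gc_band_high: float = 0.60
    target_chromosomes: tuple[str, ...] = ("21", "18", "13")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 100_000:
            raise ValueError("bin_size must be at least 100 kb")
        if not (0 < self.loess_span <= 1):
            raise ValueError("loess_span must be in (0, 1]")
        for name in ("z_positive_cutoff", "z_gray_upper", "cnv_z_cutoff", "cnv_seed_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.z_gray_upper <= self.z_positive_cutoff:
            raise ValueError("z_gray_upper must exceed z_positive_cutoff")
        if not (0 < self.ff_min < 1):
            raise ValueError("ff_min must be in (0, 1)")
        if self.min_panel_size < 2:
            raise ValueError("min_panel_size must be at least 2")
        if self.cnv_min_windows < 1:
            raise ValueError("cnv_min_windows must be at least 1")

    def to_file(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` text file."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {
            "bin_size": int, "min_panel_size": int, "seed": int,
            "cnv_min_windows": int,
            "loess_span": float, "z_positive_cutoff": float,
            "z_gray_upper": float, "ff_min": float, "cnv_z_cutoff": float,
            "cnv_seed_z": float, "gc_band_low": float, "gc_band_high": float,
        }
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key == "target_chromosomes":
                kwargs[key] = tuple(s.strip() for s in val.split(",") if s.strip())
            else:
                kwargs[key] = casts[key](val)
        return cls(**kwargs)
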