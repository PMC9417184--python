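"""Run configuration: every geometric cutoff and screen parameter in one
place, loadable from a flat ``key = value`` text file, with CLI flags
overriding file values.  A snapshot of the active configuration is embedded
in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path


@dataclass
class RunConfig:
    # interface geometry (Angstrom / degrees)
    contact_cutoff: float = 5.5
    hbond_cutoff: float = 3.6
    salt_bridge_cutoff: float = 4.0
    orientation_distance: float = 9.0
    orientation_angle: float = 90.0
    # scattering analysis
    qrg_limit: float = 1.5
    rg_tolerance: float = 0.05
    granularity: str = "residue"
    # design screen
    n_samples: int = 50
    n_finalists: int = 5
    jitter_sigma: float = 0.3
    relax_radius: float = 12.0
    pair_cutoff: float = 8.0
    clash_distance: float = 3.0
    clash_weight: float = 10.0
    hbond_weight: float = 1.0
    salt_bridge_weight: float = 2.0
    # misc
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` file ('#' comments)."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            if key == "granularity":
                kwargs[key] = value
            elif key in ("n_samples", "n_finalists", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def with_overrides(self, **overrides) -> "RunConfig":
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def show(self) -> str:
        return "\n".join(f"{key} = {value}" for key, value in self.to_dict().items())
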