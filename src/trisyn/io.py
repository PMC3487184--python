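"""Run outputs: tidy CSVs, JSON summaries and a reproducibility manifest."""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd

from .config import SimulationConfig, config_hash
from .errors import TrisynError

__all__ = ["RunManifest", "write_outputs"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Determinism contract: same config hash + seed => identical checksums."""

    config_sha256: str
    seed: int
    package_version: str
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def write_outputs(outdir: str | Path, cfg: SimulationConfig, seed: int,
                  tables: dict[str, pd.DataFrame] | None = None,
                  summary: dict | None = None, force: bool = False) -> RunManifest:
    """Write tables (CSV), a JSON summary, the resolved config and a manifest.

    Refuses to overwrite an existing non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise TrisynError(f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("trisyn")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = RunManifest(config_sha256=config_hash(cfg), seed=seed,
                           package_version=version)
    cfg.to_yaml(outdir / "config.yaml")
    manifest.files["config.yaml"] = _sha256(outdir / "config.yaml")
    for name, df in (tables or {}).items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        manifest.files[path.name] = _sha256(path)
    if summary is not None:
        path = outdir / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
        manifest.files[path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
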