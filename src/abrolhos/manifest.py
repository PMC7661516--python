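"""Run manifests: a JSON record of what produced each output directory."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, subcommand: str, seed: int | None,
                   config: dict, inputs: dict[str, str | Path],
                   artifacts: list[str]) -> Path:
    """Write ``manifest.json`` into ``out_dir`` and return its path.

    ``inputs`` maps a logical name to a file path; each gets a sha256
    digest so a re-run can verify it is looking at the same data.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "seed": seed,
        "config": config,
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in inputs.items()},
        "artifacts": sorted(artifacts),
        "timestamp_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "package_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
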