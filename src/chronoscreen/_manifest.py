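"""Run manifests: every output directory records what produced it."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from . import __version__

MANIFEST_NAME = "manifest.json"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir,
    command: str,
    params: dict,
    inputs: list | None = None,
    seed: int | None = None,
    status: str = "ok",
    failure_point: str | None = None,
) -> Path:
    """Write (or overwrite) the single manifest of an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package": "chronoscreen",
        "version": __version__,
        "seed": seed,
        "params": {k: repr(v) if not _jsonable(v) else v for k, v in params.items()},
        "inputs": {
            str(p): _digest(Path(p)) for p in (inputs or []) if Path(p).is_file()
        },
        "status": status,
        "failure_point": failure_point,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = outdir / MANIFEST_NAME
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
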