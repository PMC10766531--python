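"""Run manifests: a JSON record written atomically next to every output."""

from __future__ import annotations

import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

from importlib.metadata import PackageNotFoundError, version

__all__ = ["write_manifest"]


def _code_version() -> str:
    try:
        return version("srdtrans")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int,
    inputs: list[str],
    outputs: list[str],
    name: str = "manifest.json",
) -> Path:
    """Write the manifest atomically (temp file + rename) and return its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "code_version": _code_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2)
        target = out_dir / name
        os.replace(tmp, target)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return target
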