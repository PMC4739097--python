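"""Small shared helpers: atomic file writes and run manifests."""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path


@contextmanager
def atomic_write(path):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_manifest(out_dir, subcommand: str, params: dict, version: str) -> Path:
    """Echo the effective run configuration next to the outputs.

    Deliberately contains no timestamps so that repeated runs on the same
    inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "tinseq",
        "version": version,
        "subcommand": subcommand,
        "parameters": {k: _jsonable(v) for k, v in sorted(params.items())},
    }
    path = out_dir / f"{subcommand}.manifest.json"
    with atomic_write(path) as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    return v
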