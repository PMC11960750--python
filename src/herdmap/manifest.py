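"""Reproducible run manifests: every CLI invocation records its resolved
parameters, input digests, seed and tool version next to its outputs."""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone
from typing import Mapping, Optional, Sequence


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str,
    subcommand: str,
    parameters: Mapping,
    inputs: Sequence[str] = (),
    seed: Optional[int] = None,
) -> str:
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "parameters": {k: v for k, v in sorted(parameters.items())},
        "inputs": {os.path.basename(p): sha256_file(p) for p in inputs},
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path
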