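"""Run manifests: reproducibility records for command-line runs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["RunManifest"]


@dataclass
class RunManifest:
    command: str
    seed: int | None = None
    config_hash: str | None = None
    package_version: str = ""
    started: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    finished: str | None = None
    outputs: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @staticmethod
    def hash_payload(payload) -> str:
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def add_output(self, path: Path) -> None:
        self.outputs.append(str(path))

    def write(self, out_dir: Path) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2))
        return path
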