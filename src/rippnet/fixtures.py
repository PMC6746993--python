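"""Shipped example fixtures and their regeneration machinery.

The package ships two tiny synthetic FASTA files (used by the documentation
examples and the integration tests) together with a checksum manifest.
Because they are produced by :mod:`rippnet.synthetic` from recorded seeds,
they can be regenerated byte-identically at any time and verified against
the manifest to detect drift.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

from .synthetic import SyntheticSpec, generate_imbalanced

MANIFEST_NAME = "manifest.json"

# fixture registry: name -> generation parameters
FIXTURES = {
    "example": {
        "n_positive": 40,
        "ratio": 2,
        "substitution_prob": 0.1,
        "seed": 2019,
        "description": "40 motif-bearing positives and 80 composition-matched negatives",
    },
}


class FixtureError(RuntimeError):
    pass


def examples_dir() -> Path:
    return Path(resources.files("rippnet") / "examples")


def _write_fasta(pset, path: Path) -> None:
    with open(path, "w") as fh:
        for rec in pset:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def regenerate_fixtures(directory: Path | None = None) -> dict:
    """Rebuild every fixture from its recorded seed and write the manifest."""
    directory = Path(directory) if directory else examples_dir()
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, params in FIXTURES.items():
        spec = SyntheticSpec(
            n_positive=params["n_positive"],
            substitution_prob=params["substitution_prob"],
            seed=params["seed"],
        )
        positives, negatives = generate_imbalanced(spec, ratio=params["ratio"])
        files = {}
        for suffix, pset in (("pos", positives), ("neg", negatives)):
            path = directory / f"{name}.{suffix}.fasta"
            _write_fasta(pset, path)
            files[path.name] = _sha256(path)
        manifest[name] = {"params": params, "files": files}
    with open(directory / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def verify_fixtures(directory: Path | None = None) -> None:
    """Check every fixture file against the manifest; raise naming drift."""
    directory = Path(directory) if directory else examples_dir()
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FixtureError(f"missing fixture manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    for name, entry in manifest.items():
        for filename, digest in entry["files"].items():
            path = directory / filename
            if not path.exists():
                raise FixtureError(f"fixture {name!r}: missing file {filename}")
            if _sha256(path) != digest:
                raise FixtureError(f"fixture {name!r}: checksum mismatch in {filename}")
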