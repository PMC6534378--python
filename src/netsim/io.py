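"""Persistence: canonical JSON save/load, exports, run manifests.

JSON is the single persistence dialect.  Canonical form sorts keys and
writes numbers at full precision, so saving the same object twice
yields byte-identical files and a stable content hash.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

from .build import Network
from .diagnostics import BuildError, Diagnostic
from .specs import canonical_json

__all__ = [
    "save_json", "load_json", "save_network", "load_network",
    "spec_hash", "write_manifest", "export_spikes_tsv", "export_lfp_csv",
]

FORMAT_VERSION = "netsim-net-1"


def save_json(obj, path):
    text = canonical_json(obj)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
        fh.write("\n")
    return path


def load_json(path):
    try:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    except (json.JSONDecodeError, OSError) as err:
        raise BuildError(Diagnostic(str(path),
                                    f"cannot load JSON: {err}"))


def spec_hash(spec):
    """Stable content hash of a spec document."""
    return hashlib.sha256(
        canonical_json(spec).encode("utf-8")).hexdigest()


def save_network(network, path):
    """Persist an instantiated network (cells, conns, stims) so it can
    be reloaded and simulated without re-instantiation."""
    doc = dict(network.todict())
    doc["formatVersion"] = FORMAT_VERSION
    return save_json(doc, path)


def load_network(path):
    doc = load_json(path)
    version = doc.get("formatVersion")
    if version != FORMAT_VERSION:
        raise BuildError(Diagnostic(
            str(path),
            f"network file version {version!r} does not match reader "
            f"version {FORMAT_VERSION!r}"))
    return Network.fromdict(doc)


def export_spikes_tsv(output, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("spike_time_ms\tgid\n")
        for t, g in zip(output["spkt"], output["spkid"]):
            fh.write(f"{t!r}\t{g}\n")
    return path


def export_lfp_csv(output, path):
    lfp = output.get("lfp")
    if lfp is None:
        return None
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(["t_ms"] + [f"electrode{i}_uV"
                                      for i in range(len(lfp))]) + "\n")
        for k, t in enumerate(output["t"]):
            row = [repr(t)] + [repr(ch[k]) for ch in lfp]
            fh.write(",".join(row) + "\n")
    return path


def write_manifest(out_dir, spec, seeds, files, version):
    manifest = {
        "specHash": spec_hash(spec),
        "toolVersion": version,
        "seeds": seeds,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": sorted(os.path.basename(f) for f in files if f),
    }
    path = os.path.join(out_dir, "manifest.json")
    save_json(manifest, path)
    return path
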