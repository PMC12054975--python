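"""Sketch file serialization.

One JSON document per line, one sketch per document.  64-bit hash values
are stored as decimal strings so JSON readers with double-precision
number parsing cannot corrupt them.  Round-tripping any sketch through
save/load reproduces it bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

from .hll import HLLSketch
from .kssd import KssdSketch
from .minhash import MinHashSketch
from .orderminhash import OMHSketch

__all__ = ["save_sketches", "load_sketches"]

_CLASSES = {
    "minhash": MinHashSketch,
    "omh": OMHSketch,
    "kssd": KssdSketch,
    "hll": HLLSketch,
}

AnySketch = MinHashSketch | OMHSketch | KssdSketch | HLLSketch


def save_sketches(sketches: list[AnySketch], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sk in sketches:
            fh.write(json.dumps(sk.to_dict(), separators=(",", ":")) + "\n")


def load_sketches(path: str | Path) -> list[AnySketch]:
    out: list[AnySketch] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                algo = d["algorithm"]
                cls = _CLASSES[algo]
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}: line {ln}: not a valid sketch record ({exc})")
            out.append(cls.from_dict(d))
    return out
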