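"""Access to packaged configuration and fixture files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def read_text(*relpath: str) -> str:
    node = resources.files(__package__) / "data"
    for part in relpath:
        node = node / part
    return node.read_text()


def path(*relpath: str) -> Path:
    node = resources.files(__package__) / "data"
    for part in relpath:
        node = node / part
    return Path(str(node))
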