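"""Transparent tree-text sources: literal strings, plaintext files, gzip files.

Gzip is detected from the magic bytes (0x1f 0x8b), never from the file
extension, so ``my_tree.nwk`` that happens to be compressed still loads.
"""

from __future__ import annotations

import gzip
import os
import zlib
from pathlib import Path
from typing import Union

TreeSource = Union[str, os.PathLike]

_GZIP_MAGIC = b"\x1f\x8b"


def read_source(source: TreeSource) -> str:
    """Resolve a tree source to its text.

    ``source`` may be a literal string containing the data, the path of a
    plaintext file, or the path of a gzip-compressed file. A ``str`` is
    treated as a path when a file of that name exists; otherwise it is taken
    as literal data.
    """
    if isinstance(source, os.PathLike):
        return _read_file(Path(source))
    if isinstance(source, str):
        # newlines never occur in a sane path; cheap guard against huge strings
        if "\n" not in source and "(" not in source and os.path.isfile(source):
            return _read_file(Path(source))
        return source
    raise TypeError(f"unsupported tree source type: {type(source).__name__}")


def _read_file(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(2)
        fh.seek(0)
        raw = fh.read()
    if head == _GZIP_MAGIC:
        try:
            raw = gzip.decompress(raw)
        except (EOFError, gzip.BadGzipFile, zlib.error) as exc:
            raise OSError(f"corrupt gzip stream in {path}: {exc}") from exc
    return raw.decode("utf-8")


def write_text(path: Union[str, os.PathLike], text: str) -> None:
    """Write text, gzip-compressing iff the path ends in ``.gz``."""
    path = Path(path)
    data = text.encode("utf-8")
    if path.suffix == ".gz":
        with gzip.open(path, "wb") as fh:
            fh.write(data)
    else:
        path.write_bytes(data)
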