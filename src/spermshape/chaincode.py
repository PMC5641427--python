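"""Freeman chain-code records and the ``.chc`` text dialect.

A chain code is a start pixel plus a sequence of 8-direction digits in
the mathematical (y-up) frame::

    0 = +x   1 = +x+y   2 = +y   3 = -x+y
    4 = -x   5 = -x-y   6 = -y   7 = +x-y

File dialect (one record per line, ASCII, single-space separated)::

    specimen_id start_x start_y code1 code2 ... codeK

``#`` begins a comment line; blank lines are ignored; the reader
tolerates CRLF endings.  Chains must be closed (their summed
displacement is zero).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import geometry

logger = logging.getLogger(__name__)

__all__ = [
    "ChainCode",
    "DIR_VECTORS",
    "parse_chc",
    "write_chc",
    "chain_to_contour",
    "contours_to_csv",
    "read_contour_csv",
]

#: Freeman code -> (dx, dy) unit step in the y-up frame.
DIR_VECTORS = {
    0: (1, 0), 1: (1, 1), 2: (0, 1), 3: (-1, 1),
    4: (-1, 0), 5: (-1, -1), 6: (0, -1), 7: (1, -1),
}
_STEPS = np.array([DIR_VECTORS[c] for c in range(8)])


@dataclass
class ChainCode:
    """Start pixel plus Freeman 8-direction codes (lossless grid contour)."""

    specimen_id: str
    start: tuple[int, int]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.size and not np.all((self.codes >= 0) & (self.codes <= 7)):
            raise ValueError(f"chain '{self.specimen_id}' has codes outside 0..7")

    def displacement(self) -> tuple[int, int]:
        if self.codes.size == 0:
            return (0, 0)
        d = _STEPS[self.codes].sum(axis=0)
        return int(d[0]), int(d[1])

    @property
    def is_closed(self) -> bool:
        return self.displacement() == (0, 0)

    def reversed(self) -> "ChainCode":
        """Same boundary traversed the other way (codes reversed, +4 mod 8)."""
        return ChainCode(self.specimen_id, self.start,
                         (self.codes[::-1] + 4) % 8)

    def oriented_ccw(self) -> "ChainCode":
        """Return this chain, reversed if its decoded polygon is clockwise."""
        if self.codes.size and geometry.signed_area(_decode(self)) < 0:
            return self.reversed()
        return self


def _decode(chain: ChainCode) -> np.ndarray:
    steps = _STEPS[chain.codes]
    verts = np.vstack([[0, 0], np.cumsum(steps, axis=0)])[:-1]
    return verts + np.asarray(chain.start, dtype=float)


def parse_chc(source) -> list[ChainCode]:
    """Read chain-code records from a path, text stream, or string.

    Validates closure of every chain and the 0..7 digit alphabet;
    duplicate specimen ids are deterministically suffixed (``_2``, ...).
    """
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    chains: list[ChainCode] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.rstrip("\r\n").strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ValueError(f"line {lineno}: expected 'id x y codes...', "
                             f"got {len(tokens)} fields")
        sid = tokens[0]
        try:
            x, y = int(tokens[1]), int(tokens[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer start pixel") from exc
        codes = []
        for tok in tokens[3:]:
            if tok not in {"0", "1", "2", "3", "4", "5", "6", "7"}:
                raise ValueError(
                    f"line {lineno}: chain digit '{tok}' outside 0-7")
            codes.append(int(tok))
        chain = ChainCode(sid, (x, y), np.asarray(codes, dtype=np.int8))
        if not chain.is_closed:
            raise ValueError(
                f"chain '{sid}' is not closed: summed displacement "
                f"{chain.displacement()} != (0, 0)")
        if sid in seen:
            seen[sid] += 1
            chain.specimen_id = f"{sid}_{seen[sid]}"
            logger.warning("duplicate specimen id %r renamed to %r",
                           sid, chain.specimen_id)
        else:
            seen[sid] = 1
        chains.append(chain)
    return chains


def write_chc(chains: list[ChainCode], sink) -> None:
    """Write records in the canonical dialect (LF endings, single spaces)."""
    lines = []
    for chain in chains:
        if not chain.is_closed:
            raise ValueError(f"chain '{chain.specimen_id}' is not closed")
        fields = [chain.specimen_id, str(int(chain.start[0])),
                  str(int(chain.start[1]))] + [str(int(c)) for c in chain.codes]
        lines.append(" ".join(fields))
    text = "".join(line + "\n" for line in lines)
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


def chain_to_contour(chain: ChainCode) -> np.ndarray:
    """Decode a closed chain into a CCW polygon of grid vertices.

    The first vertex equals the chain start; the closing vertex is not
    duplicated.  Clockwise chains are reversed; self-crossing boundaries
    are accepted with a warning; zero-area chains raise ``ValueError``.
    """
    if not chain.is_closed:
        raise ValueError(f"chain '{chain.specimen_id}' is not closed")
    if chain.codes.size < 3:
        raise ValueError(f"chain '{chain.specimen_id}' has zero area")
    verts = _decode(chain)
    area = geometry.signed_area(verts)
    if area == 0:
        raise ValueError(f"chain '{chain.specimen_id}' encloses zero area")
    if area < 0:
        verts = np.vstack([verts[:1], verts[1:][::-1]])
    if not geometry.is_simple(verts):
        logger.warning("chain '%s' decodes to a self-crossing polygon",
                       chain.specimen_id)
    return verts


def contours_to_csv(contours: dict[str, np.ndarray], sink) -> None:
    """Write contours as CSV (specimen_id, vertex_index, x, y)."""
    import pandas as pd

    frames = []
    for sid, contour in contours.items():
        c = geometry.as_contour(contour)
        frames.append(pd.DataFrame({
            "specimen_id": sid,
            "vertex_index": np.arange(c.shape[0]),
            "x": c[:, 0],
            "y": c[:, 1],
        }))
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["specimen_id", "vertex_index", "x", "y"])
    df.to_csv(sink, index=False)


def read_contour_csv(source) -> dict[str, np.ndarray]:
    """Read contours from the CSV layout written by :func:`contours_to_csv`."""
    import pandas as pd

    df = pd.read_csv(source)
    required = {"specimen_id", "vertex_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"contour CSV must have columns {sorted(required)}")
    out: dict[str, np.ndarray] = {}
    for sid, sub in df.groupby("specimen_id", sort=False):
        sub = sub.sort_values("vertex_index")
        out[str(sid)] = sub[["x", "y"]].to_numpy(dtype=float)
    return out
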