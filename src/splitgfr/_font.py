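"""Built-in 7x10 bitmap glyphs for digits, decimal point and minus sign.

Used both for rendering synthetic structured reports and as the matched-filter
templates when parsing them back, so the digit round trip is exact by
construction.
"""

from __future__ import annotations

import numpy as np

_GLYPH_ART = {
    "0": [
        ".###.",
        "#...#",
        "#..##",
        "#.#.#",
        "##..#",
        "#...#",
        ".###.",
    ],
    "1": [
        "..#..",
        ".##..",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        ".###.",
    ],
    "2": [
        ".###.",
        "#...#",
        "....#",
        "...#.",
        "..#..",
        ".#...",
        "#####",
    ],
    "3": [
        "#####",
        "...#.",
        "..#..",
        "...#.",
        "....#",
        "#...#",
        ".###.",
    ],
    "4": [
        "...#.",
        "..##.",
        ".#.#.",
        "#..#.",
        "#####",
        "...#.",
        "...#.",
    ],
    "5": [
        "#####",
        "#....",
        "####.",
        "....#",
        "....#",
        "#...#",
        ".###.",
    ],
    "6": [
        "..##.",
        ".#...",
        "#....",
        "####.",
        "#...#",
        "#...#",
        ".###.",
    ],
    "7": [
        "#####",
        "....#",
        "...#.",
        "..#..",
        ".#...",
        ".#...",
        ".#...",
    ],
    "8": [
        ".###.",
        "#...#",
        "#...#",
        ".###.",
        "#...#",
        "#...#",
        ".###.",
    ],
    "9": [
        ".###.",
        "#...#",
        "#...#",
        ".####",
        "....#",
        "...#.",
        ".##..",
    ],
    ".": [
        ".....",
        ".....",
        ".....",
        ".....",
        ".....",
        ".##..",
        ".##..",
    ],
    "-": [
        ".....",
        ".....",
        ".....",
        ".###.",
        ".....",
        ".....",
        ".....",
    ],
}

GLYPH_HEIGHT = 10
GLYPH_WIDTH = 7
GLYPH_PITCH = 8  # one blank column between glyphs


def _render_glyph(art: list[str]) -> np.ndarray:
    g = np.zeros((GLYPH_HEIGHT, GLYPH_WIDTH), dtype=bool)
    for r, row in enumerate(art):
        for c, ch in enumerate(row):
            if ch == "#":
                g[r + 1, c + 1] = True  # 1-px padding inside the cell
    return g


GLYPHS: dict[str, np.ndarray] = {ch: _render_glyph(a) for ch, a in _GLYPH_ART.items()}


def default_templates() -> dict[str, np.ndarray]:
    """Copies of the built-in glyph patches, keyed by character."""
    return {ch: g.copy() for ch, g in GLYPHS.items()}
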