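"""Biomarker gene panel handling.

The TGx-DDI biomarker is a fixed panel of 64 genes whose transcriptional
response separates DNA damage-inducing (DDI) from non-DDI exposures.  The
published panel is identified by gene symbols; this package ships a
synthetic stand-in panel (``BM001`` ... ``BM064``) so that the whole
pipeline is runnable without external data, and accepts a user-supplied
symbol list for work with a real panel.
"""

from __future__ import annotations

from pathlib import Path


def biomarker_panel(n_genes: int = 64) -> list[str]:
    """Return the default synthetic biomarker panel of ``n_genes`` symbols."""
    if n_genes < 1:
        raise ValueError("panel must contain at least one gene")
    width = max(3, len(str(n_genes)))
    return [f"BM{i:0{width}d}" for i in range(1, n_genes + 1)]


def load_panel(path: str | Path) -> list[str]:
    """Load a biomarker panel from a plain text file, one gene symbol per line.

    Blank lines and ``#`` comments are ignored.  Duplicate symbols are an
    error: the classifier treats the panel as an ordered set.
    """
    symbols: list[str] = []
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            symbols.append(sym)
    if not symbols:
        raise ValueError(f"panel file {path} contains no gene symbols")
    if len(set(symbols)) != len(symbols):
        dups = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"duplicate gene symbols in panel: {dups}")
    return symbols
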