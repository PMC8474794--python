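"""Gene-set membership filtering and mouse-to-human symbol mapping."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class GeneSet:
    """Named set of gene symbols with optional per-symbol category."""

    name: str
    symbols: set[str]
    category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = {_norm(s) for s in self.symbols}
        self.category = {_norm(k): v for k, v in self.category.items()}

    def __contains__(self, symbol: str) -> bool:
        return _norm(symbol) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Load a two-column TSV (symbol, category); category optional."""
    df = pd.read_csv(path, sep="\t")
    symbols = df.iloc[:, 0].astype(str)
    category = {}
    if df.shape[1] > 1:
        category = dict(zip(symbols, df.iloc[:, 1].astype(str)))
    return GeneSet(name or str(path), set(symbols), category)


def bundled_matrisome() -> GeneSet:
    """The matrisome symbol list shipped with the package."""
    ref = importlib.resources.files("matrisig") / "data" / "matrisome_mouse.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_gene_set(path, name="matrisome")


def filter_by_gene_set(de: pd.DataFrame, gs: GeneSet) -> pd.DataFrame:
    """Retain DE probes whose gene symbol is in the set.

    Probe multiplicity is preserved: several probes of one member gene
    all stay. Comparison is case-insensitive after whitespace stripping.
    """
    if "gene_symbol" not in de.columns:
        raise ValueError("DE table lacks a gene_symbol column")
    mask = de["gene_symbol"].map(lambda s: _norm(s) in gs.symbols)
    return de.loc[mask]


@dataclass
class OrthologMap:
    """Mouse-to-human symbol mapping.

    The default rule upper-cases the mouse symbol; explicit override
    entries win over the rule. With ``default_rule=False`` symbols
    without an override are reported as unmapped instead.
    """

    overrides: dict[str, str] = field(default_factory=dict)
    default_rule: bool = True

    def __post_init__(self) -> None:
        normed: dict[str, str] = {}
        for mouse, human in self.overrides.items():
            key = _norm(mouse)
            val = _norm(human)
            if key in normed and normed[key] != val:
                raise ValueError(
                    f"conflicting ortholog overrides for {mouse!r}: "
                    f"{normed[key]} vs {val}"
                )
            normed[key] = val
        self.overrides = normed


def read_ortholog_map(path, default_rule: bool = True) -> OrthologMap:
    df = pd.read_csv(path, sep="\t")
    overrides = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return OrthologMap(overrides, default_rule=default_rule)


def map_orthologs(symbols, om: OrthologMap | None = None) -> tuple[list[str], list[str]]:
    """Map mouse symbols to human symbols.

    Returns ``(mapped, unmapped)``: ``mapped`` is the human symbol per
    input (in order, unmapped entries skipped), ``unmapped`` lists inputs
    with no override when the default rule is off.
    """
    om = om or OrthologMap()
    mapped: list[str] = []
    unmapped: list[str] = []
    for sym in symbols:
        key = _norm(sym)
        if key in om.overrides:
            mapped.append(om.overrides[key])
        elif om.default_rule:
            mapped.append(key)
        else:
            unmapped.append(str(sym))
    return mapped, unmapped
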