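"""Gene-program knowledge: GMT parsing and decoder-mask construction.

A gene program (GP) is a named set of genes (a pathway, a marker list, a
hand-curated signature).  Programs are wired into the decoder through two
binary matrices over the dataset's gene axis:

* ``B`` (genes x programs) — membership: ``B[i, j] = 1`` iff gene *i* belongs
  to program *j*.  Hard-membership columns pin decoder weights outside the
  program to exactly zero.
* ``M = 1 - B`` — the soft-mask complement: entries with ``M[i, j] = 1`` are
  allowed but L1-penalised, letting the model enrich incomplete programs.
  A fully unconstrained (sparse) program has an all-zero ``B`` column and an
  all-one ``M`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneSetCollection", "GPMask", "read_gmt", "build_masks"]

#: roles a decoder column can take
ROLE_HARD = "hard"
ROLE_SOFT = "soft"
ROLE_UNCONSTRAINED = "unconstrained-sparse"


class GMTParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Ordered collection of (program name, gene list) pairs.

    Invariants: names unique, no empty program, genes de-duplicated
    (first occurrence kept).
    """

    sets: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self):
        names = [n for n, _ in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate program name(s): {dupes}")
        deduped = []
        for name, genes in self.sets:
            seen: set[str] = set()
            uniq = [g for g in genes if not (g in seen or seen.add(g))]
            if not uniq:
                raise ValueError(f"program {name!r} is empty")
            deduped.append((name, uniq))
        self.sets = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return [n for n, _ in self.sets]

    def __getitem__(self, name: str) -> list[str]:
        for n, genes in self.sets:
            if n == name:
                return genes
        raise KeyError(name)


@dataclass
class GPMask:
    """Binary membership matrix ``B`` and soft-mask complement ``M``.

    Rows follow ``gene_names`` (the row order of the expression matrix's
    gene axis); columns follow ``program_names``.  ``membership_mode`` gives
    one role per program column.  ``orphan_genes`` lists genes that belong
    to no retained program (reported, never dropped — the caller decides).
    """

    program_names: list[str]
    gene_names: list[str]
    B: np.ndarray
    M: np.ndarray
    membership_mode: list[str]
    orphan_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=np.int8)
        self.M = np.asarray(self.M, dtype=np.int8)
        n_genes, n_prog = len(self.gene_names), len(self.program_names)
        if self.B.shape != (n_genes, n_prog) or self.M.shape != (n_genes, n_prog):
            raise ValueError("B/M shape does not match gene_names x program_names")
        if not np.all((self.B + self.M) == 1):
            raise ValueError("B and M must be complementary (B + M = 1 elementwise)")

    @property
    def n_programs(self) -> int:
        return len(self.program_names)

    def genes_of(self, program: str) -> list[str]:
        j = self.program_names.index(program)
        return [g for g, b in zip(self.gene_names, self.B[:, j]) if b]


def read_gmt(path, dialect: str = "auto", gene_names=None) -> GeneSetCollection:
    """Parse a tab-delimited gene-set file.

    Two dialects exist in the wild: the standard GMT layout
    ``name<TAB>description<TAB>gene...`` and a headerless variant
    ``name<TAB>gene...``.  With ``dialect="auto"`` the second field of each
    line is treated as a description unless it looks like a gene: it is a
    member of ``gene_names`` (when a gene universe is supplied) or it
    re-occurs among the remaining fields of the line.  ``dialect="gmt"`` /
    ``dialect="headerless"`` force one interpretation.

    Empty files yield an empty collection.  Lines with fewer than two fields
    and duplicate set names raise :class:`GMTParseError`.
    """
    if dialect not in ("auto", "gmt", "headerless"):
        raise ValueError(f"unknown dialect {dialect!r}")
    universe = set(gene_names) if gene_names is not None else None
    sets: list[tuple[str, list[str]]] = []
    names_seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected at least 2 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            if name in names_seen:
                raise GMTParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            names_seen.add(name)
            if dialect == "headerless":
                genes = fields[1:]
            elif dialect == "gmt":
                genes = fields[2:]
            else:
                second = fields[1]
                second_is_gene = (
                    second in universe if universe is not None else second in fields[2:]
                )
                genes = fields[1:] if second_is_gene else fields[2:]
            if not genes:
                raise GMTParseError(
                    f"{path}: line {lineno}: set {name!r} has no genes"
                )
            sets.append((name, genes))
    return GeneSetCollection(sets)


def build_masks(
    sets: GeneSetCollection,
    gene_names,
    min_genes: int = 12,
    max_genes: int | None = None,
    soft: bool = False,
    case_insensitive: bool = False,
    n_unconstrained: int = 0,
    unconstrained_prefix: str = "unconstrained",
) -> GPMask:
    """Intersect programs with the dataset gene axis and build ``B``/``M``.

    Programs retaining fewer than ``min_genes`` members (or more than
    ``max_genes`` if set) are dropped; program order is preserved.  ``soft``
    selects soft membership for every curated column.  ``n_unconstrained``
    appends that many all-free sparse columns (all-zero ``B``, all-one
    ``M``).  Matching is exact and case-sensitive unless
    ``case_insensitive`` is set.
    """
    gene_names = list(gene_names)
    if not gene_names:
        raise ValueError("gene_names must be non-empty")
    if case_insensitive:
        index = {}
        for i, g in enumerate(gene_names):
            index.setdefault(g.upper(), i)
        lookup = lambda g: index.get(g.upper())  # noqa: E731
    else:
        index = {g: i for i, g in enumerate(gene_names)}
        lookup = index.get

    kept_names: list[str] = []
    kept_cols: list[np.ndarray] = []
    for name, genes in sets.sets:
        rows = sorted({r for g in genes if (r := lookup(g)) is not None})
        if len(rows) < min_genes:
            continue
        if max_genes is not None and len(rows) > max_genes:
            continue
        col = np.zeros(len(gene_names), dtype=np.int8)
        col[rows] = 1
        kept_names.append(name)
        kept_cols.append(col)

    if not kept_cols and n_unconstrained == 0:
        raise ValueError(
            f"no gene program retained >= {min_genes} genes from the dataset "
            "gene axis; lower min_genes or check gene-name matching"
        )

    modes = [ROLE_SOFT if soft else ROLE_HARD] * len(kept_names)
    for k in range(n_unconstrained):
        kept_names.append(f"{unconstrained_prefix}_{k}")
        kept_cols.append(np.zeros(len(gene_names), dtype=np.int8))
        modes.append(ROLE_UNCONSTRAINED)

    B = np.stack(kept_cols, axis=1) if kept_cols else np.zeros((len(gene_names), 0), np.int8)
    M = (1 - B).astype(np.int8)
    covered = B.sum(axis=1) > 0
    orphans = [g for g, c in zip(gene_names, covered) if not c]
    return GPMask(
        program_names=kept_names,
        gene_names=gene_names,
        B=B,
        M=M,
        membership_mode=modes,
        orphan_genes=orphans,
    )
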