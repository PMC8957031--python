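"""Gene signatures: domain types, GMT/TSV I/O, ortholog translation,
truncation, and cross-tissue/species comparison.

A drug signature is the set of genes a treatment perturbs in one species,
tissue, dose, and duration, optionally split into up- and downregulated
halves. Symbol matching is case-insensitive everywhere (human symbols are
conventionally uppercase, rodent symbols capitalized); outputs preserve the
casing of the first occurrence seen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import SIGNATURE_CAP

SPECIES = ("human", "mouse", "rat", "other")

SIGNATURE_TSV_COLUMNS = ["id", "species", "tissue", "dose", "duration", "gene", "direction", "stat"]


def _ordered_unique(symbols: Iterable[str], context: str = "") -> tuple[str, ...]:
    """Deduplicate symbols case-insensitively, keeping first casing and order."""
    seen: dict[str, str] = {}
    for sym in symbols:
        sym = str(sym).strip()
        if not sym:
            raise ValueError(f"empty gene symbol{' in ' + context if context else ''}")
        seen.setdefault(sym.upper(), sym)
    return tuple(seen.values())


def _upper(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(g.upper() for g in genes)


@dataclass(frozen=True)
class GeneSignature:
    """A drug's (or disease's) gene set with optional direction split.

    ``directed=False`` marks an undirected set that happens to be stored in
    ``up_genes`` (e.g. a GMT line without an ``_up``/``_down`` suffix).
    """

    id: str
    species: str = "other"
    tissue: str = ""
    dose: str | None = None
    duration: str | None = None
    source: str | None = None
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()
    ranking_stat: Mapping[str, float] | None = None
    directed: bool = True
    n_dropped: int = 0
    n_expanded: int = 0

    def __post_init__(self):
        if not str(self.id).strip():
            raise ValueError("signature id must be non-empty")
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        object.__setattr__(self, "up_genes", _ordered_unique(self.up_genes, self.id))
        object.__setattr__(self, "down_genes", _ordered_unique(self.down_genes, self.id))
        both = self.up_upper & self.down_upper
        if both:
            raise ValueError(
                f"signature {self.id!r}: genes in both directions: {sorted(both)[:5]}"
            )
        if self.ranking_stat is not None:
            stat = {str(k).upper(): float(v) for k, v in self.ranking_stat.items()}
            object.__setattr__(self, "ranking_stat", stat)

    @property
    def up_upper(self) -> frozenset[str]:
        return _upper(self.up_genes)

    @property
    def down_upper(self) -> frozenset[str]:
        return _upper(self.down_genes)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    @property
    def all_upper(self) -> frozenset[str]:
        return self.up_upper | self.down_upper

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.id, self.species, self.tissue, self.dose or "", self.duration or "")


@dataclass(frozen=True)
class GeneSet:
    """An undirected disease / ADR / toxicity gene set."""

    id: str
    genes: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "genes", _ordered_unique(self.genes, self.id))
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")

    @property
    def upper(self) -> frozenset[str]:
        return _upper(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


class OrthologMap:
    """Many-to-many mapping from source-species to target-species symbols."""

    def __init__(self, pairs: Mapping[str, Iterable[str]]):
        self._map: dict[str, tuple[str, ...]] = {}
        for src, targets in pairs.items():
            src = str(src).strip()
            if not src:
                raise ValueError("empty source symbol in ortholog map")
            targets = _ordered_unique(targets, f"orthologs of {src}")
            if not targets:
                raise ValueError(f"no targets for ortholog source {src!r}")
            self._map[src.upper()] = targets

    def __len__(self) -> int:
        return len(self._map)

    def get(self, symbol: str) -> tuple[str, ...]:
        return self._map.get(symbol.upper(), ())

    @classmethod
    def read(cls, path: str | Path) -> "OrthologMap":
        """Read a 2-column TSV (source, target), one pair per row."""
        df = pd.read_csv(path, sep="\t", dtype=str, header=0)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: ortholog map needs 2 columns (source, target)")
        pairs: dict[str, list[str]] = {}
        for src, tgt in zip(df.iloc[:, 0], df.iloc[:, 1]):
            pairs.setdefault(str(src).strip().upper(), []).append(str(tgt).strip())
        return cls(pairs)


class SignatureLibrary:
    """A collection of GeneSignature keyed by (id, species, tissue, dose, duration)."""

    def __init__(self, signatures: Iterable[GeneSignature] = ()):
        self._sigs: dict[tuple, GeneSignature] = {}
        for sig in signatures:
            self.add(sig)

    def add(self, sig: GeneSignature) -> None:
        if sig.key in self._sigs:
            existing = self._sigs[sig.key]
            if existing.up_upper != sig.up_upper or existing.down_upper != sig.down_upper:
                raise ValueError(f"duplicate signature key {sig.key} with conflicting genes")
            return
        self._sigs[sig.key] = sig

    def __len__(self) -> int:
        return len(self._sigs)

    def __iter__(self):
        return iter(self.sorted())

    def sorted(self) -> list[GeneSignature]:
        return [self._sigs[k] for k in sorted(self._sigs)]

    def get(self, key: tuple) -> GeneSignature:
        return self._sigs[key]

    def filter(self, **metadata: str) -> list[GeneSignature]:
        """Select signatures matching every given metadata field exactly
        (trimmed, case-folded); returns a deterministic sorted list."""
        fields = {k: str(v).strip().casefold() for k, v in metadata.items()}
        out = []
        for sig in self.sorted():
            values = {
                "id": sig.id, "species": sig.species, "tissue": sig.tissue,
                "dose": sig.dose or "", "duration": sig.duration or "",
            }
            if all(str(values[k]).strip().casefold() == v for k, v in fields.items()):
                out.append(sig)
        return out

    def universe(self) -> frozenset[str]:
        """Union of all genes (uppercased) across the library."""
        out: set[str] = set()
        for sig in self._sigs.values():
            out |= sig.all_upper
        return frozenset(out)


# ---------------------------------------------------------------------------
# File I/O


def _parse_gmt(path: Path) -> SignatureLibrary:
    halves: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name = parts[0].strip()
        genes = [g for chunk in parts[2:] for g in chunk.split() if g.strip()]
        if not name:
            raise ValueError(f"{path}:{lineno}: empty set name")
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
        lower = name.lower()
        if lower.endswith("_up"):
            base, direction = name[:-3], "up"
        elif lower.endswith("_down"):
            base, direction = name[:-5], "down"
        else:
            base, direction = name, None
        if base not in halves:
            halves[base] = {"up": [], "down": [], "directed": False}
            order.append(base)
        if direction is None:
            halves[base]["up"].extend(genes)
        else:
            halves[base]["directed"] = True
            halves[base][direction].extend(genes)
    lib = SignatureLibrary()
    for base in order:
        h = halves[base]
        try:
            lib.add(GeneSignature(id=base, up_genes=h["up"], down_genes=h["down"],
                                  directed=h["directed"]))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return lib


def _parse_signature_tsv(path: Path) -> SignatureLibrary:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.shape[1] == 0:
        return SignatureLibrary()
    missing = [c for c in SIGNATURE_TSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lib = SignatureLibrary()
    meta_cols = ["id", "species", "tissue", "dose", "duration"]
    df = df.fillna({"dose": "", "duration": "", "tissue": "", "direction": "none"})
    for key, grp in df.groupby(meta_cols, sort=True, dropna=False):
        sig_id, species, tissue, dose, duration = key
        up, down, undirected = [], [], []
        stats: dict[str, float] = {}
        for row in grp.itertuples(index=False):
            gene = str(row.gene).strip()
            direction = str(row.direction).strip().lower()
            if direction == "up":
                up.append(gene)
            elif direction == "down":
                down.append(gene)
            elif direction in {"none", "", "nan"}:
                undirected.append(gene)
            else:
                raise ValueError(
                    f"{path}: signature {sig_id!r}: bad direction {row.direction!r}"
                )
            stat = getattr(row, "stat", None)
            if stat is not None and str(stat) not in {"", "nan"}:
                stats[gene.upper()] = float(stat)
        directed = bool(up or down)
        try:
            lib.add(GeneSignature(
                id=str(sig_id), species=str(species), tissue=str(tissue),
                dose=str(dose) or None, duration=str(duration) or None,
                up_genes=up + undirected if not directed else up,
                down_genes=down,
                ranking_stat=stats or None, directed=directed,
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return lib


def read_signatures(path: str | Path, format: str = "gmt") -> SignatureLibrary:
    """Read a signature library from GMT or long-format TSV.

    GMT dialect: one gene set per line (``name<TAB>description<TAB>genes...``)
    with direction encoded by an ``_up``/``_down`` name suffix; a name
    without a suffix is an undirected set. TSV dialect: columns
    id, species, tissue, dose, duration, gene, direction, stat.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gmt":
        return _parse_gmt(path)
    if format == "tsv":
        return _parse_signature_tsv(path)
    raise ValueError(f"unknown signature format {format!r}")


def write_signatures(library: SignatureLibrary, path: str | Path, format: str = "gmt") -> None:
    """Write a library in the same dialects ``read_signatures`` accepts."""
    path = Path(path)
    if format == "gmt":
        lines = []
        for sig in library:
            if not sig.directed:
                lines.append("\t".join([sig.id, "."] + list(sig.up_genes)))
                continue
            if sig.up_genes:
                lines.append("\t".join([f"{sig.id}_up", "."] + list(sig.up_genes)))
            if sig.down_genes:
                lines.append("\t".join([f"{sig.id}_down", "."] + list(sig.down_genes)))
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    if format == "tsv":
        rows = []
        for sig in library:
            stat = sig.ranking_stat or {}
            for gene in sig.up_genes:
                direction = "up" if sig.directed else "none"
                rows.append([sig.id, sig.species, sig.tissue, sig.dose or "",
                             sig.duration or "", gene, direction, stat.get(gene.upper(), "")])
            for gene in sig.down_genes:
                rows.append([sig.id, sig.species, sig.tissue, sig.dose or "",
                             sig.duration or "", gene, "down", stat.get(gene.upper(), "")])
        pd.DataFrame(rows, columns=SIGNATURE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unknown signature format {format!r}")


def read_gene_set(path: str | Path, set_id: str | None = None) -> GeneSet:
    """Read an undirected gene set: one symbol per line (``#`` comments allowed)."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    return GeneSet(id=set_id or path.stem, genes=genes)


# ---------------------------------------------------------------------------
# Operations


def translate_species(sig: GeneSignature, omap: OrthologMap) -> GeneSignature:
    """Map each gene to all its orthologs (many-to-many union), dropping
    unmapped genes; direction is preserved and drop/expansion counts are
    recorded on the returned signature."""
    if len(omap) == 0:
        raise ValueError("ortholog map is empty")
    dropped = 0
    expanded = 0
    stats = sig.ranking_stat or {}
    new_stats: dict[str, float] = {}

    def translate(genes: Sequence[str]) -> list[str]:
        nonlocal dropped, expanded
        out: list[str] = []
        for gene in genes:
            targets = omap.get(gene)
            if not targets:
                dropped += 1
                continue
            if len(targets) > 1:
                expanded += 1
            out.extend(targets)
            if gene.upper() in stats:
                for t in targets:
                    prev = new_stats.get(t.upper())
                    val = stats[gene.upper()]
                    new_stats[t.upper()] = val if prev is None else min(prev, val)
        return out

    up = translate(sig.up_genes)
    down = translate(sig.down_genes)
    # a gene may map into both halves through shared orthologs; up wins
    up_set = {g.upper() for g in up}
    down = [g for g in down if g.upper() not in up_set]
    if not up and not down:
        raise ValueError(f"signature {sig.id!r}: ortholog translation left no genes")
    return replace(sig, up_genes=tuple(up), down_genes=tuple(down),
                   ranking_stat=new_stats or None, n_dropped=dropped, n_expanded=expanded)


def truncate_signature(sig: GeneSignature, cap: int = SIGNATURE_CAP) -> GeneSignature:
    """Keep the ``cap`` genes with smallest ranking statistic (FDR/p),
    pooled across both directions; ties break by uppercased symbol order."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    if sig.size <= cap:
        return sig
    stats = sig.ranking_stat
    if stats is None:
        raise ValueError(f"signature {sig.id!r} exceeds cap {cap} but has no ranking_stat")
    missing = sig.all_upper - set(stats)
    if missing:
        raise ValueError(f"signature {sig.id!r}: no ranking_stat for {sorted(missing)[:5]}")
    pooled = sorted(sig.all_genes, key=lambda g: (stats[g.upper()], g.upper()))
    keep = {g.upper() for g in pooled[:cap]}
    return replace(
        sig,
        up_genes=tuple(g for g in sig.up_genes if g.upper() in keep),
        down_genes=tuple(g for g in sig.down_genes if g.upper() in keep),
        ranking_stat={g: v for g, v in stats.items() if g in keep},
    )


def compare_across_groups(
    sigs: Sequence[GeneSignature],
    denominator: str = "union",
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Pairwise overlap percentages and UpSet-style exclusive region counts.

    Overlap percentage between direction-pooled sets A, B is
    ``100*|A∩B|/denom`` with ``denom`` the union (Jaccard, default), the
    smaller set, or the mean set size. Exclusive regions assign each gene of
    the overall union to exactly one subset-combination of the inputs.
    """
    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures to compare")
    if denominator not in {"union", "min", "mean"}:
        raise ValueError(f"unknown denominator {denominator!r}")
    labels: list[str] = []
    for i, sig in enumerate(sigs):
        label = sig.id if sig.id not in labels else f"{sig.id}#{i}"
        labels.append(label)
    pooled = [sig.all_upper for sig in sigs]

    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(pooled), 2):
        inter = len(a & b)
        if denominator == "union":
            denom = len(a | b)
        elif denominator == "min":
            denom = min(len(a), len(b))
        else:
            denom = (len(a) + len(b)) / 2
        pct = 100.0 * inter / denom if denom else 0.0
        rows.append([labels[i], labels[j], len(a), len(b), inter, pct])
    table = pd.DataFrame(
        rows, columns=["id_a", "id_b", "size_a", "size_b", "n_overlap", "overlap_pct"]
    )

    regions: dict[tuple[str, ...], int] = {}
    union = frozenset().union(*pooled)
    for gene in union:
        members = tuple(labels[i] for i, s in enumerate(pooled) if gene in s)
        regions[members] = regions.get(members, 0) + 1
    return table, regions
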