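"""Gene-set collections and the GMT carrier format."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (each a de-duplicated, ordered list of gene ids)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            seen: set[str] = set()
            deduped = [g for g in genes if not (g in seen or seen.add(g))]
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>...`` per line.

    Duplicate genes within a set are dropped with a warning; lines with no
    genes are skipped with a warning; fewer than 3 fields is a format error.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                logger.warning("%s:%d: set %r has no genes; dropped", path, lineno, name)
                continue
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(genes)) != len(genes):
                logger.warning("%s:%d: duplicate genes in set %r de-duplicated", path, lineno, name)
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, "na", *genes]) + "\n")
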