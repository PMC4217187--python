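"""Dictionary-based literature annotation: gene tagging, rsID detection, MeSH diseases.

Re-implements the minimal text-mining stack the ranking needs: a gene-name
dictionary built from (gene_id, names) records with ambiguity preserved and
misleading names filtered; a case-insensitive, adjacent-token, longest-match
tagger over a simple alphanumeric tokenization; word-boundary rsID detection
restricted to a catalog of known intergenic SNPs; and disease assignment from
MeSH metadata filtered to the cancer (Neoplasms) subtree by tree-number
prefix. No species disambiguation, abbreviation expansion or free-text
disease NER is attempted.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .genome import SnpLocus

logger = logging.getLogger(__name__)

#: Names ending with these words are dropped from the gene dictionary: they
#: almost always denote a phenotype, not the gene itself.
DEFAULT_BANNED_SUFFIXES = frozenset({"disease", "syndrome", "susceptibility"})

#: Compact default English stopword set (overridable; see `read_stopwords`).
DEFAULT_STOPWORDS = frozenset("""
a about after all also an and any are as at be been between both but by can
did do for from had has have if in into is it its may more most no not of on
one only or other our per so such than that the their then there these this
to two under was we were which while with within
""".split())

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_RSID_TOKEN_RE = re.compile(r"\brs[0-9]+\b")
_RSID_TOKEN_RE_I = re.compile(r"\brs[0-9]+\b", re.IGNORECASE)


@dataclass(frozen=True)
class MeshTerm:
    label: str
    tree_numbers: tuple[str, ...] = ()


@dataclass(frozen=True)
class Document:
    """One citation: identifier, title+abstract text, and MeSH metadata."""

    doc_id: str
    text: str
    mesh_terms: tuple[MeshTerm, ...] = ()


@dataclass(frozen=True)
class GeneMention:
    surface: str
    start: int
    end: int
    gene_ids: frozenset[str]


@dataclass(frozen=True)
class AnnotatedDocument:
    """A citation reduced to the concept sets the scoring stages consume."""

    doc_id: str
    gene_ids: frozenset[str]
    rsids: frozenset[str]
    disease_terms: frozenset[str]


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Case-folded alphanumeric tokens with character spans."""
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class GeneDictionary:
    """Surface-name -> gene_id dictionary with token-sequence keys.

    A name shared by several genes maps to all of them (ambiguity is
    preserved; disambiguation is out of scope at abstract level).
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, ...], set[str]] = {}
        self.max_tokens: int = 0

    def add(self, name: str, gene_id: str) -> None:
        key = tuple(tok for tok, _, _ in tokenize(name))
        if not key:
            return
        self._entries.setdefault(key, set()).add(gene_id)
        self.max_tokens = max(self.max_tokens, len(key))

    def lookup(self, key: tuple[str, ...]) -> Optional[frozenset[str]]:
        ids = self._entries.get(key)
        return frozenset(ids) if ids else None

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return tuple(tok for tok, _, _ in tokenize(name)) in self._entries


def build_dictionary(
    gene_records: Iterable[tuple[str, Sequence[str]]],
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    banned_suffixes: frozenset[str] = DEFAULT_BANNED_SUFFIXES,
) -> GeneDictionary:
    """Build the tagging dictionary from (gene_id, names) records.

    Names are case-normalized; single-token stopwords and names whose last
    word is a banned suffix are filtered out. An empty post-filter
    dictionary is a warning, not an error.
    """
    d = GeneDictionary()
    for gene_id, names in gene_records:
        for name in names:
            tokens = [tok for tok, _, _ in tokenize(name)]
            if not tokens:
                continue
            if tokens[-1] in banned_suffixes:
                continue
            if len(tokens) == 1 and tokens[0] in stopwords:
                continue
            d.add(name, str(gene_id))
    if len(d) == 0:
        logger.warning("gene dictionary is empty after filtering")
    return d


def tag_genes(text: str, dictionary: GeneDictionary) -> list[GeneMention]:
    """Longest-match dictionary scan over adjacent tokens, case-insensitive.

    At each token position the longest matching token n-gram wins and the
    scan resumes after it, so mention spans never overlap. Surfaces are
    reported verbatim from the text.
    """
    tokens = tokenize(text)
    mentions: list[GeneMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for length in range(min(dictionary.max_tokens, len(tokens) - i), 0, -1):
            key = tuple(tok for tok, _, _ in tokens[i:i + length])
            ids = dictionary.lookup(key)
            if ids:
                start = tokens[i][1]
                end = tokens[i + length - 1][2]
                mentions.append(GeneMention(text[start:end], start, end, ids))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def detect_rsids(text: str, catalog: Mapping[str, SnpLocus] | Iterable[SnpLocus],
                 case_sensitive_prefix: bool = True) -> frozenset[str]:
    """rsIDs mentioned in the text that are known intergenic SNPs.

    Tokens matching ``rs<digits>`` at word boundaries are kept only when the
    catalog lists them as intergenic. The ``rs`` prefix is matched
    case-sensitively by default (the dbSNP convention).
    """
    if not isinstance(catalog, Mapping):
        catalog = {s.rsid: s for s in catalog}
    pattern = _RSID_TOKEN_RE if case_sensitive_prefix else _RSID_TOKEN_RE_I
    found = set()
    for m in pattern.finditer(text):
        rsid = m.group(0).lower() if not case_sensitive_prefix else m.group(0)
        snp = catalog.get(rsid)
        if snp is not None and snp.is_intergenic:
            found.add(rsid)
    return frozenset(found)


def disease_terms(doc: Document, mesh_table: Mapping[str, Sequence[str]],
                  subtree_prefix: str = "C04") -> frozenset[str]:
    """MeSH labels of the document lying under the Neoplasms subtree.

    Tree numbers come from the document's own metadata when present,
    otherwise from ``mesh_table``; a label unknown to both is skipped with a
    warning. The subtree prefix defaults to ``C04`` (Neoplasms).
    """
    kept = set()
    for term in doc.mesh_terms:
        numbers = term.tree_numbers or tuple(mesh_table.get(term.label, ()))
        if not numbers:
            logger.warning("document %s: unknown MeSH label %r", doc.doc_id, term.label)
            continue
        if any(num.startswith(subtree_prefix) for num in numbers):
            kept.add(term.label)
    return frozenset(kept)


def annotate_document(doc: Document, dictionary: GeneDictionary,
                      catalog: Mapping[str, SnpLocus],
                      mesh_table: Mapping[str, Sequence[str]],
                      subtree_prefix: str = "C04") -> AnnotatedDocument:
    mentions = tag_genes(doc.text, dictionary)
    gene_ids = frozenset(gid for m in mentions for gid in m.gene_ids)
    return AnnotatedDocument(
        doc_id=doc.doc_id,
        gene_ids=gene_ids,
        rsids=detect_rsids(doc.text, catalog),
        disease_terms=disease_terms(doc, mesh_table, subtree_prefix),
    )


def annotate_corpus(docs: Iterable[Document], dictionary: GeneDictionary,
                    catalog: Mapping[str, SnpLocus] | Iterable[SnpLocus],
                    mesh_table: Mapping[str, Sequence[str]],
                    subtree_prefix: str = "C04") -> list[AnnotatedDocument]:
    """Reduce every document to its gene/rsID/disease sets (order-independent)."""
    if not isinstance(catalog, Mapping):
        catalog = {s.rsid: s for s in catalog}
    return [
        annotate_document(doc, dictionary, catalog, mesh_table, subtree_prefix)
        for doc in docs
    ]


# ---------------------------------------------------------------------------
# Resource readers / writers
# ---------------------------------------------------------------------------

def read_corpus_jsonl(path) -> list[Document]:
    """Corpus JSON-lines: {"doc_id","title","abstract","mesh":[{label,tree_numbers}]}."""
    docs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            text = " ".join(p for p in (rec.get("title"), rec.get("abstract")) if p)
            mesh = tuple(
                MeshTerm(m["label"], tuple(m.get("tree_numbers", ())))
                for m in rec.get("mesh", ())
            )
            docs.append(Document(str(rec["doc_id"]), text, mesh))
    return docs


def write_corpus_jsonl(docs: Iterable[Document], path) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            rec = {
                "doc_id": doc.doc_id,
                "title": "",
                "abstract": doc.text,
                "mesh": [
                    {"label": t.label, "tree_numbers": list(t.tree_numbers)}
                    for t in doc.mesh_terms
                ],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_medline_xml(path) -> list[Document]:
    """Minimal MEDLINE-like XML reader (PMID, ArticleTitle, AbstractText, MeshHeading)."""
    from lxml import etree

    docs = []
    tree = etree.parse(str(path))
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//PMID") or ""
        title = article.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (el.text or "") for el in article.iter("AbstractText")
        )
        mesh = tuple(
            MeshTerm(el.findtext("DescriptorName") or "")
            for el in article.iter("MeshHeading")
        )
        docs.append(Document(pmid, f"{title} {abstract}".strip(), mesh))
    return docs


def read_dictionary_tsv(path, **kwargs) -> GeneDictionary:
    """Dictionary TSV: name<TAB>gene_id, one synonym per line."""
    records: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{Path(path).name}:{lineno}: expected name<TAB>gene_id")
            records.setdefault(parts[1], []).append(parts[0])
    return build_dictionary(records.items(), **kwargs)


def write_dictionary_tsv(gene_records: Iterable[tuple[str, Sequence[str]]], path) -> None:
    with open(path, "w") as fh:
        for gene_id, names in gene_records:
            for name in names:
                fh.write(f"{name}\t{gene_id}\n")


def read_mesh_tsv(path) -> dict[str, tuple[str, ...]]:
    """MeSH TSV: label<TAB>tree_number[;tree_number...]."""
    table: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            label, _, numbers = line.partition("\t")
            table[label] = tuple(n for n in numbers.split(";") if n)
    return table


def write_mesh_tsv(table: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for label in sorted(table):
            fh.write(f"{label}\t{';'.join(table[label])}\n")


def read_stopwords(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(w.strip().lower() for w in fh if w.strip())
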