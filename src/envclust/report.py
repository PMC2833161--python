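"""Static HTML reports for annotated clusters.

One summary page per cluster (general info + top significant terms per
category) and one detail page per category listing every scored term
with its contributing proteins and, for literature terms, the documents
and their text.  Output is plain static HTML with relative internal
links; external links (structure/protein/literature databases) are
URL-pattern templated.  Rendering is deterministic: identical inputs
yield byte-identical files.
"""

from __future__ import annotations

import html
from pathlib import Path

from .annotate import DEFAULT_ENTROPY_CUTOFF, LITERATURE_CATEGORIES, TermScore
from .coherence import KnowledgeCorpus
from .select import ClusterRecord

DEFAULT_URL_PATTERNS = {
    "structure": "https://www.rcsb.org/structure/{id}",
    "protein": "https://www.uniprot.org/uniprotkb/{id}",
    "document": "https://pubmed.ncbi.nlm.nih.gov/{id}/",
}

_STYLE = (
    "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
    "td,th{border:1px solid #999;padding:4px 8px}th{background:#eee}</style>"
)


def _page(title: str, body: str) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title>{_STYLE}</head>\n"
        f"<body><h1>{html.escape(title)}</h1>\n{body}\n</body></html>\n"
    )


def _ext_link(kind: str, ident: str, patterns: dict) -> str:
    url = patterns.get(kind, "").format(id=ident)
    e = html.escape(ident)
    return f"<a href='{html.escape(url)}'>{e}</a>" if url else e


def render_cluster_html(record: ClusterRecord, term_scores: dict[str, list[TermScore]],
                        corpus: KnowledgeCorpus, out_dir,
                        url_patterns: dict | None = None,
                        entropy_cutoff: float = DEFAULT_ENTROPY_CUTOFF,
                        top_n: int = 10) -> list[Path]:
    """Write one summary page and one detail page per category.

    Returns the written file paths (summary first)."""
    patterns = {**DEFAULT_URL_PATTERNS, **(url_patterns or {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sites = "".join(
        f"<li>{html.escape(str(s))} ({_ext_link('structure', s.structure_id, patterns)})</li>"
        for s in record.member_sites
    )
    proteins = "".join(
        f"<li>{_ext_link('protein', p, patterns)}</li>" for p in record.member_proteins
    )
    body = [
        "<h2>General information</h2><table>",
        f"<tr><th>size N</th><td>{record.N}</td></tr>",
        f"<tr><th>node correlation C</th><td>{record.C:.4f}</td></tr>",
        f"<tr><th>functional coherence F</th><td>{record.F:.4f}</td></tr>",
        f"<tr><th>score S</th><td>{record.S:.4f}</td></tr>",
        "</table>",
        f"<h2>Member sites</h2><ul>{sites}</ul>",
        f"<h2>Member proteins</h2><ul>{proteins}</ul>",
        "<h2>Top terms per category</h2>",
    ]
    for category in sorted(term_scores):
        detail_name = f"{record.cluster_id}_{category}.html"
        terms = term_scores[category]
        body.append(f"<h3>{html.escape(category)} "
                    f"(<a href='{html.escape(detail_name)}'>details</a>)</h3>")
        if not terms:
            body.append("<p>no significant terms</p>")
        else:
            rows = []
            for t in terms[:top_n]:
                es = "" if t.entropy_score is None else f"{t.entropy_score:.3f}"
                rows.append(
                    f"<tr><td>{html.escape(t.term)}</td><td>{t.k}/{t.n}</td>"
                    f"<td>{t.p_corrected:.3g}</td><td>{es}</td></tr>"
                )
            body.append(
                "<table><tr><th>term</th><th>cluster</th><th>corrected p</th>"
                "<th>entropy score</th></tr>" + "".join(rows) + "</table>"
            )
        written.append(
            _write_detail(record, category, terms, corpus, out_dir / detail_name,
                          patterns, entropy_cutoff)
        )
    summary = out_dir / f"{record.cluster_id}.html"
    summary.write_text(_page(f"Cluster {record.cluster_id}", "\n".join(body)))
    return [summary] + written


def _write_detail(record, category, terms, corpus, path: Path, patterns,
                  entropy_cutoff) -> Path:
    body = []
    if not terms:
        body.append("<p>no significant terms</p>")
    for t in terms:
        body.append(f"<h2>{html.escape(t.term)}</h2>")
        es = ""
        if t.entropy_score is not None:
            flag = " (significant)" if t.entropy_score >= entropy_cutoff else ""
            es = f", entropy score {t.entropy_score:.4f}{flag}"
        body.append(
            f"<p>{t.k} of {t.n} cluster proteins; background {t.K}/{t.M}; "
            f"raw p {t.p_raw:.3g}, corrected p {t.p_corrected:.3g}{es}</p>"
        )
        items = []
        for p in t.contributors:
            entry = _ext_link("protein", p, patterns)
            if category in LITERATURE_CATEGORIES:
                docs = []
                for d in sorted(corpus.protein_docs.get(p, ())):
                    text = corpus.documents.get(d, "")
                    if f" {t.term} " in f" {text.lower()} " or t.term in text.lower():
                        docs.append(
                            f"<li>{_ext_link('document', d, patterns)}: "
                            f"<small>{html.escape(text[:400])}</small></li>"
                        )
                if docs:
                    entry += f"<ul>{''.join(docs)}</ul>"
            items.append(f"<li>{entry}</li>")
        body.append(f"<ul>{''.join(items)}</ul>")
    path.write_text(_page(f"{record.cluster_id} — {category}", "\n".join(body)))
    return path


def render_index(records: list[ClusterRecord], out_dir) -> Path:
    """Index page linking every cluster summary."""
    out_dir = Path(out_dir)
    rows = "".join(
        f"<tr><td><a href='{r.cluster_id}.html'>{r.cluster_id}</a></td>"
        f"<td>{r.N}</td><td>{r.C:.3f}</td><td>{r.F:.3f}</td><td>{r.S:.3f}</td></tr>"
        for r in records
    )
    body = ("<table><tr><th>cluster</th><th>N</th><th>C</th><th>F</th><th>S</th></tr>"
            + rows + "</table>")
    path = out_dir / "index.html"
    path.write_text(_page("Selected clusters", body))
    return path
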