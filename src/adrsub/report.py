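"""Static HTML and XML result reports.

The HTML report summarizes, for one drug-event pair, whatever stages were
run: filtering counts per source (citation lists grouped by publication
type with a per-year table), the linking-protein table with mean affinities
and overlap p/q values, the connecting-pathway list, and the network
proximity summary. Rendered with stdlib string formatting; no template
engine dependency.
"""

from __future__ import annotations

from html import escape
from pathlib import Path
from typing import Mapping, Optional, Sequence

from lxml import etree

from .filtering import FilterReport
from .network import PathTestResult
from .pathways import ConnectingPathway
from .proteins import SubstantiationResult


def _filter_section(reports: Mapping[str, FilterReport]) -> str:
    parts = ["<h2>Signal filtering</h2>"]
    parts.append("<table border='1'><tr><th>Source</th><th>Records</th></tr>")
    for source, rep in reports.items():
        n = "NA" if not rep.available else str(len(rep.matched_ids))
        parts.append(f"<tr><td>{escape(source)}</td><td>{n}</td></tr>")
    parts.append("</table>")
    for source, rep in reports.items():
        if not rep.available or not rep.matched_ids:
            continue
        parts.append(f"<h3>{escape(source)}</h3>")
        if rep.by_publication_type:
            parts.append("<p>Citations grouped by publication type:</p><ul>")
            for pt in sorted(rep.by_publication_type):
                ids = ", ".join(escape(i) for i in rep.by_publication_type[pt])
                parts.append(f"<li><b>{escape(pt)}</b>: {ids}</li>")
            parts.append("</ul>")
        if rep.per_year:
            parts.append(
                "<table border='1'><tr><th>Year</th><th>Citations</th></tr>"
            )
            for year in sorted(rep.per_year):
                parts.append(f"<tr><td>{year}</td><td>{rep.per_year[year]}</td></tr>")
            parts.append("</table>")
        if rep.statistic is not None:
            parts.append(
                f"<p>Sentence co-occurrence chi-square = {rep.statistic:.4g}, "
                f"p = {rep.p_value:.4g}</p>"
            )
    return "\n".join(parts)


def _substantiation_section(result: SubstantiationResult) -> str:
    parts = ["<h2>Substantiation through proteins</h2>"]
    q = "not adjusted" if result.q_value is None else f"{result.q_value:.4g}"
    parts.append(
        f"<p>Overlap k = {result.k} of drug profile m = {result.m} and event "
        f"profile n = {result.n} in a universe of N = {result.N}; "
        f"p = {result.p_value:.4g}, q = {q}.</p>"
    )
    if not result.linking:
        parts.append("<p>No linking proteins.</p>")
        return "\n".join(parts)
    parts.append(
        "<table border='1'><tr><th>Gene</th><th>UniProt</th>"
        "<th>mean pKi</th><th>mean pIC50</th><th>via metabolite</th></tr>"
    )
    for lp in result.linking:
        pki = _mean_affinity(lp, "pKi")
        pic50 = _mean_affinity(lp, "pIC50")
        parts.append(
            f"<tr><td>{escape(lp.gene_symbol)}</td><td>{escape(lp.uniprot_acc)}</td>"
            f"<td>{pki}</td><td>{pic50}</td>"
            f"<td>{'yes' if lp.via_metabolite else 'no'}</td></tr>"
        )
    parts.append("</table>")
    return "\n".join(parts)


def _mean_affinity(lp, kind: str) -> str:
    values = [
        r.affinity_value
        for r in lp.drug_evidence
        if r.affinity_kind == kind and r.affinity_value is not None
    ]
    return f"{sum(values) / len(values):.2f}" if values else ""


def _pathway_section(pathways: Sequence[ConnectingPathway]) -> str:
    parts = ["<h2>Substantiation through pathways</h2>"]
    if not pathways:
        parts.append("<p>No connecting pathways.</p>")
        return "\n".join(parts)
    parts.append("<ul>")
    for pw in pathways:
        parts.append(
            f"<li><b>{escape(pw.pathway_name)}</b> ({escape(pw.pathway_id)}): "
            f"drug proteins {', '.join(sorted(pw.drug_proteins))}; "
            f"event proteins {', '.join(sorted(pw.event_proteins))}</li>"
        )
    parts.append("</ul>")
    return "\n".join(parts)


def _pathtest_section(result: PathTestResult) -> str:
    t = "undefined" if result.t_statistic is None else f"{result.t_statistic:.4g}"
    return (
        "<h2>Network proximity</h2>"
        f"<p>Observed mean shortest path {result.observed_mean:.3f} hops over "
        f"{result.n_pairs_used} pairs ({result.n_pairs_unreachable} unreachable); "
        f"random ensemble mean {result.null_mean:.3f}; t = {t}, "
        f"one-sided p = {result.p_value:.4g}, empirical p = {result.empirical_p:.4g}.</p>"
    )


def write_html_report(
    path: str | Path,
    title: str = "Drug safety signal report",
    filter_reports: Optional[Mapping[str, FilterReport]] = None,
    substantiation: Optional[SubstantiationResult] = None,
    pathways: Optional[Sequence[ConnectingPathway]] = None,
    pathtest: Optional[PathTestResult] = None,
) -> None:
    sections = []
    if filter_reports:
        sections.append(_filter_section(filter_reports))
    if substantiation is not None:
        sections.append(_substantiation_section(substantiation))
    if pathways is not None:
        sections.append(_pathway_section(pathways))
    if pathtest is not None:
        sections.append(_pathtest_section(pathtest))
    body = "\n".join(sections) if sections else "<p>No evidence found.</p>"
    html = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{escape(title)}</title></head>\n"
        f"<body><h1>{escape(title)}</h1>\n{body}\n</body></html>\n"
    )
    Path(path).write_text(html, encoding="utf-8")


def write_xml_result(
    path: str | Path,
    substantiation: SubstantiationResult,
) -> None:
    """Flat XML dump of one substantiation result."""
    root = etree.Element("substantiationResult")
    etree.SubElement(root, "drug").set("atc", substantiation.drug_atc)
    ev = etree.SubElement(root, "event")
    ev.set("code", substantiation.event.code)
    ev.set("name", substantiation.event.name)
    for cui in substantiation.event.cui_list:
        etree.SubElement(ev, "cui").text = cui
    st = etree.SubElement(root, "overlap")
    st.set("k", str(substantiation.k))
    st.set("m", str(substantiation.m))
    st.set("n", str(substantiation.n))
    st.set("N", str(substantiation.N))
    st.set("p", repr(substantiation.p_value))
    if substantiation.q_value is not None:
        st.set("q", repr(substantiation.q_value))
    for lp in substantiation.linking:
        el = etree.SubElement(root, "linkingProtein")
        el.set("uniprot", lp.uniprot_acc)
        el.set("gene", lp.gene_symbol)
        el.set("viaMetabolite", "true" if lp.via_metabolite else "false")
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
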