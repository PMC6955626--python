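"""Synthetic pathways and annotation tables with known ground truth.

Two generators live here:

* :func:`make_toy_fixture` — a fixed pair of small pathways modeled on the
  hepatic urea cycle (a four-reaction cycle) and de novo pyrimidine
  biosynthesis (a linear chain whose first three steps are catalyzed by a
  single trifunctional gene), sharing one connector compound (a carbamoyl
  phosphate analog).  Every identifier is fictional (``cpd:CX...``,
  ``hsa:9...``) — these are structural analogs, not database records.  The
  fixture ships with a hand-enumerated manifest of node/edge counts at
  every pipeline stage, seed distances for every node, and golden export
  tables, so the whole cascade is testable end to end without downloads.

* :func:`random_pathways` / :func:`random_annotations` — seeded random
  generators producing structurally valid pathways and annotation tables
  for property-based testing (merge algebra, distance oracles, prune
  postconditions).

The random generator emulates the statistical shape of curated pathway
files — small directed reaction sets with shared compound pools, a mix of
enzymatic and relation-only genes — not the size or biochemistry of any
real database.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import (
    AnnotationTables,
    read_biofluid_table,
    read_expression_table,
    read_prognosis_table,
)
from .kgml import Pathway, parse_kgml, serialize_kgml
from .network import MetaboNetwork, NODE_METABOLITE

# --------------------------------------------------------------------------
# fixed toy fixture
# --------------------------------------------------------------------------

#: four-step cycle analogous to the urea cycle: ornithine + carbamoyl
#: phosphate -> citrulline -> argininosuccinate <-> arginine -> ornithine + urea
TOY_UREA_KGML = """\
<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:syn00001" title="Synthetic urea cycle">
  <entry id="1" name="cpd:CX000" type="compound"><graphics name="CarbamoylP-X"/></entry>
  <entry id="2" name="cpd:CX001" type="compound"><graphics name="Ornithine-X"/></entry>
  <entry id="3" name="cpd:CX002" type="compound"><graphics name="Citrulline-X"/></entry>
  <entry id="4" name="cpd:CX003" type="compound"><graphics name="ArgSuccinate-X"/></entry>
  <entry id="5" name="cpd:CX004" type="compound"><graphics name="Arginine-X"/></entry>
  <entry id="6" name="cpd:CX005" type="compound"><graphics name="Urea-X"/></entry>
  <entry id="11" name="hsa:9101" type="gene" reaction="rn:RX001"><graphics name="OTC-X"/></entry>
  <entry id="12" name="hsa:9102" type="gene" reaction="rn:RX002"><graphics name="ASS1-X"/></entry>
  <entry id="13" name="hsa:9103" type="gene" reaction="rn:RX003"><graphics name="ASL-X"/></entry>
  <entry id="14" name="hsa:9104" type="gene" reaction="rn:RX004"><graphics name="ARG1-X"/></entry>
  <reaction id="21" name="rn:RX001" type="irreversible">
    <substrate id="2" name="cpd:CX001"/>
    <substrate id="1" name="cpd:CX000"/>
    <product id="3" name="cpd:CX002"/>
  </reaction>
  <reaction id="22" name="rn:RX002" type="irreversible">
    <substrate id="3" name="cpd:CX002"/>
    <product id="4" name="cpd:CX003"/>
  </reaction>
  <reaction id="23" name="rn:RX003" type="reversible">
    <substrate id="4" name="cpd:CX003"/>
    <product id="5" name="cpd:CX004"/>
  </reaction>
  <reaction id="24" name="rn:RX004" type="irreversible">
    <substrate id="5" name="cpd:CX004"/>
    <product id="2" name="cpd:CX001"/>
    <product id="6" name="cpd:CX005"/>
  </reaction>
</pathway>
"""

#: linear chain analogous to de novo pyrimidine biosynthesis; the CAD-like
#: trifunctional gene catalyzes the first three steps and shares the
#: carbamoyl phosphate analog with the cycle above; one relation-only gene
#: provides a signaling node.
TOY_PYRIMIDINE_KGML = """\
<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:syn00002" title="Synthetic de novo pyrimidine biosynthesis">
  <entry id="1" name="cpd:CX010" type="compound"><graphics name="Glutamine-X"/></entry>
  <entry id="2" name="cpd:CX000" type="compound"><graphics name="CarbamoylP-X"/></entry>
  <entry id="3" name="cpd:CX011" type="compound"><graphics name="CarbamoylAsp-X"/></entry>
  <entry id="4" name="cpd:CX012" type="compound"><graphics name="Dihydroorotate-X"/></entry>
  <entry id="5" name="cpd:CX013" type="compound"><graphics name="Orotate-X"/></entry>
  <entry id="6" name="cpd:CX014" type="compound"><graphics name="UMP-X"/></entry>
  <entry id="11" name="hsa:9201" type="gene" reaction="rn:RY001 rn:RY002 rn:RY003"><graphics name="CAD-X"/></entry>
  <entry id="12" name="hsa:9202" type="gene" reaction="rn:RY004"><graphics name="DHODH-X"/></entry>
  <entry id="13" name="hsa:9203" type="gene" reaction="rn:RY005"><graphics name="UMPS-X"/></entry>
  <entry id="14" name="hsa:9204" type="gene"><graphics name="SIG-X"/></entry>
  <reaction id="21" name="rn:RY001" type="irreversible">
    <substrate id="1" name="cpd:CX010"/>
    <product id="2" name="cpd:CX000"/>
  </reaction>
  <reaction id="22" name="rn:RY002" type="irreversible">
    <substrate id="2" name="cpd:CX000"/>
    <product id="3" name="cpd:CX011"/>
  </reaction>
  <reaction id="23" name="rn:RY003" type="irreversible">
    <substrate id="3" name="cpd:CX011"/>
    <product id="4" name="cpd:CX012"/>
  </reaction>
  <reaction id="24" name="rn:RY004" type="irreversible">
    <substrate id="4" name="cpd:CX012"/>
    <product id="5" name="cpd:CX013"/>
  </reaction>
  <reaction id="25" name="rn:RY005" type="irreversible">
    <substrate id="5" name="cpd:CX013"/>
    <product id="6" name="cpd:CX014"/>
  </reaction>
  <relation entry1="14" entry2="11" type="PPrel">
    <subtype name="activation"/>
  </relation>
</pathway>
"""

#: one seed per pathway: the cycle gene adjacent to the connector compound
#: and the trifunctional chain gene (mirroring the CPS1/CAD anchor roles)
TOY_SEEDS = ("hsa:9101", "hsa:9201")

TOY_TISSUE = "hepatocytes"

#: 8 genes; ARG1-X and UMPS-X are not expressed in the target tissue
TOY_EXPRESSION_TSV = """\
gene_id\ttissue\tvalue
hsa:9101\thepatocytes\t12.5
hsa:9102\thepatocytes\t8.0
hsa:9103\thepatocytes\t3.1
hsa:9104\thepatocytes\t0.0
hsa:9201\thepatocytes\t6.4
hsa:9202\thepatocytes\t4.2
hsa:9203\thepatocytes\t0.0
hsa:9204\thepatocytes\t1.7
hsa:9101\tneurons\t0.3
"""

#: the two seed rows mirror the published favorable/unfavorable pattern;
#: the 0.001 row sits exactly on the strict-inequality boundary
TOY_PROGNOSIS_TSV = """\
gene_id\tdirection\tlogrank_p
hsa:9101\tfavorable\t6.93e-05
hsa:9201\tunfavorable\t1.72e-11
hsa:9102\tfavorable\t0.001
hsa:9202\tunfavorable\t0.005
"""

TOY_BIOFLUID_TSV = """\
metabolite_id\tin_normal_urine\tin_abnormal_urine
cpd:CX002\ttrue\ttrue
cpd:CX005\ttrue\ttrue
cpd:CX010\ttrue\tfalse
cpd:CX013\tfalse\ttrue
"""

_GOLDEN_NODE_TABLE = """\
node_id\tlabel\tkind\tis_seed\tdistance\texpression_value\tprognosis\tprognosis_p\turine_normal\turine_abnormal
hsa:9101\tOTC-X\tmetabolic_gene\ttrue\t0\t12.5\tfavorable\t6.93e-05\t\t
hsa:9102\tASS1-X\tmetabolic_gene\tfalse\t2\t8.0\tnone\t0.001\t\t
hsa:9201\tCAD-X\tmetabolic_gene\ttrue\t0\t6.4\tunfavorable\t1.72e-11\t\t
hsa:9202\tDHODH-X\tmetabolic_gene\tfalse\t2\t4.2\tnone\t0.005\t\t
cpd:CX000\tCarbamoylP-X\tmetabolite\tfalse\t1\t\t\t\t\t
cpd:CX001\tOrnithine-X\tmetabolite\tfalse\t1\t\t\t\t\t
cpd:CX002\tCitrulline-X\tmetabolite\tfalse\t1\t\t\t\ttrue\ttrue
cpd:CX003\tArgSuccinate-X\tmetabolite\tfalse\t3\t\t\t\t\t
cpd:CX010\tGlutamine-X\tmetabolite\tfalse\t1\t\t\t\ttrue\tfalse
cpd:CX011\tCarbamoylAsp-X\tmetabolite\tfalse\t1\t\t\t\t\t
cpd:CX012\tDihydroorotate-X\tmetabolite\tfalse\t1\t\t\t\t\t
cpd:CX013\tOrotate-X\tmetabolite\tfalse\t3\t\t\t\tfalse\ttrue
hsa:9204\tSIG-X\tsignaling_gene\tfalse\t1\t1.7\t\t\t\t
"""

_GOLDEN_EDGE_TABLE = """\
source\ttarget\tedge_type\tprovenance
cpd:CX000\thsa:9101\tsubstrate_to_gene\tsyn00001:rn:RX001
cpd:CX000\thsa:9201\tsubstrate_to_gene\tsyn00002:rn:RY002
cpd:CX001\thsa:9101\tsubstrate_to_gene\tsyn00001:rn:RX001
cpd:CX002\thsa:9102\tsubstrate_to_gene\tsyn00001:rn:RX002
cpd:CX010\thsa:9201\tsubstrate_to_gene\tsyn00002:rn:RY001
cpd:CX011\thsa:9201\tsubstrate_to_gene\tsyn00002:rn:RY003
cpd:CX012\thsa:9202\tsubstrate_to_gene\tsyn00002:rn:RY004
hsa:9101\tcpd:CX002\tgene_to_product\tsyn00001:rn:RX001
hsa:9102\tcpd:CX003\tgene_to_product\tsyn00001:rn:RX002
hsa:9201\tcpd:CX000\tgene_to_product\tsyn00002:rn:RY001
hsa:9201\tcpd:CX011\tgene_to_product\tsyn00002:rn:RY002
hsa:9201\tcpd:CX012\tgene_to_product\tsyn00002:rn:RY003
hsa:9202\tcpd:CX013\tgene_to_product\tsyn00002:rn:RY004
hsa:9204\thsa:9201\tgene_to_gene\tsyn00002:PPrel:14-11
"""

_GOLDEN_SIF = """\
cpd:CX000\tsubstrate_to_gene\thsa:9101
cpd:CX000\tsubstrate_to_gene\thsa:9201
cpd:CX001\tsubstrate_to_gene\thsa:9101
cpd:CX002\tsubstrate_to_gene\thsa:9102
cpd:CX010\tsubstrate_to_gene\thsa:9201
cpd:CX011\tsubstrate_to_gene\thsa:9201
cpd:CX012\tsubstrate_to_gene\thsa:9202
hsa:9101\tgene_to_product\tcpd:CX002
hsa:9102\tgene_to_product\tcpd:CX003
hsa:9201\tgene_to_product\tcpd:CX000
hsa:9201\tgene_to_product\tcpd:CX011
hsa:9201\tgene_to_product\tcpd:CX012
hsa:9202\tgene_to_product\tcpd:CX013
hsa:9204\tgene_to_gene\thsa:9201
"""

#: hand-enumerated ground truth for the toy fixture under the default
#: cascade (max_steps=3, undirected distances, expression threshold 0,
#: alpha=0.001, min 2 metabolite neighbors, prune to fixpoint)
TOY_MANIFEST: dict = {
    "seeds": list(TOY_SEEDS),
    "tissue": TOY_TISSUE,
    "stage_counts": {
        # stage: (n_nodes, n_metabolites, n_metabolic, n_signaling, n_edges)
        "build": (19, 11, 7, 1, 23),
        "distance_filter": (16, 10, 5, 1, 17),
        "annotate": (16, 10, 5, 1, 17),
        "expression_filter": (15, 10, 4, 1, 14),
        "prune": (13, 8, 4, 1, 14),
    },
    "distances": {
        "hsa:9101": 0, "hsa:9201": 0,
        "cpd:CX000": 1, "cpd:CX001": 1, "cpd:CX002": 1,
        "cpd:CX010": 1, "cpd:CX011": 1, "cpd:CX012": 1, "hsa:9204": 1,
        "hsa:9102": 2, "hsa:9104": 2, "hsa:9202": 2,
        "cpd:CX003": 3, "cpd:CX004": 3, "cpd:CX005": 3, "cpd:CX013": 3,
        "hsa:9103": 4, "hsa:9203": 4, "cpd:CX014": 5,
    },
    "removed_by_distance": ["cpd:CX014", "hsa:9103", "hsa:9203"],
    "removed_by_expression": ["hsa:9104"],
    "removed_by_prune": ["cpd:CX004", "cpd:CX005"],
    "final_nodes": [
        "cpd:CX000", "cpd:CX001", "cpd:CX002", "cpd:CX003", "cpd:CX010",
        "cpd:CX011", "cpd:CX012", "cpd:CX013",
        "hsa:9101", "hsa:9102", "hsa:9201", "hsa:9202", "hsa:9204",
    ],
    "golden_node_table": _GOLDEN_NODE_TABLE,
    "golden_edge_table": _GOLDEN_EDGE_TABLE,
    "golden_sif": _GOLDEN_SIF,
}


def make_toy_fixture() -> tuple[list[Pathway], AnnotationTables, dict]:
    """The packaged urea-cycle/pyrimidine-chain fixture with its manifest."""
    pathways = [parse_kgml(TOY_UREA_KGML), parse_kgml(TOY_PYRIMIDINE_KGML)]
    tables = AnnotationTables(
        expression=read_expression_table(TOY_EXPRESSION_TSV),
        prognosis=read_prognosis_table(TOY_PROGNOSIS_TSV),
        biofluid=read_biofluid_table(TOY_BIOFLUID_TSV),
    )
    return pathways, tables, dict(TOY_MANIFEST)


def write_fixture_dir(out_dir: str | Path) -> list[Path]:
    """Materialize the toy fixture as KGML + TSV files plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in (
        ("syn00001.kgml", TOY_UREA_KGML),
        ("syn00002.kgml", TOY_PYRIMIDINE_KGML),
        ("expression.tsv", TOY_EXPRESSION_TSV),
        ("prognosis.tsv", TOY_PROGNOSIS_TSV),
        ("biofluid.tsv", TOY_BIOFLUID_TSV),
        ("golden_node_table.tsv", _GOLDEN_NODE_TABLE),
        ("golden_edge_table.tsv", _GOLDEN_EDGE_TABLE),
        ("golden_network.sif", _GOLDEN_SIF),
    ):
        path = out / name
        path.write_text(text, encoding="utf-8", newline="\n")
        written.append(path)
    manifest_lines = [f"seeds={','.join(TOY_SEEDS)}", f"tissue={TOY_TISSUE}"]
    for stage, counts in TOY_MANIFEST["stage_counts"].items():
        manifest_lines.append(f"count.{stage}={','.join(map(str, counts))}")
    for node, dist in sorted(TOY_MANIFEST["distances"].items()):
        manifest_lines.append(f"distance.{node}={dist}")
    path = out / "manifest.txt"
    path.write_text("\n".join(manifest_lines) + "\n", encoding="utf-8", newline="\n")
    written.append(path)
    return written


# --------------------------------------------------------------------------
# seeded random generators
# --------------------------------------------------------------------------


class SynthConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the random pathway/annotation generators.

    Defaults give a small curated-pathway-like shape: a handful of
    reactions over a shared compound pool, a couple of gene-gene
    relations, mostly expressed genes, a minority of prognostic genes and
    about half of metabolites urine-detectable.
    """

    n_compounds: int = 10
    n_genes: int = 8
    n_reactions: int = 8
    p_reversible: float = 0.25
    n_relations: int = 2
    seed: int = 0
    frac_expressed: float = 0.8
    frac_prognostic: float = 0.3
    frac_urine: float = 0.5
    n_pathways: int = 1

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_genes", "n_reactions", "n_relations"):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be >= 0")
        for name in ("p_reversible", "frac_expressed", "frac_prognostic", "frac_urine"):
            if not 0 <= getattr(self, name) <= 1:
                raise SynthConfigError(f"{name} must be in [0, 1]")
        if self.n_pathways < 1:
            raise SynthConfigError("n_pathways must be >= 1")
        if self.n_reactions > 0 and (self.n_compounds < 2 or self.n_genes < 1):
            raise SynthConfigError(
                "reactions require at least 2 compounds and 1 gene"
            )
        if self.n_relations > 0 and self.n_genes < 2:
            raise SynthConfigError("relations require at least 2 genes")


def random_pathways(config: SynthConfig) -> list[Pathway]:
    """Generate structurally valid random pathways, deterministic per seed.

    Reactions and relations are distributed round-robin over
    ``n_pathways`` pathway files drawing compounds and genes from shared
    pools, so multi-pathway configurations exercise merging and
    deduplication.  Every reaction has at least one substrate, one product
    and one catalyzing gene; substrates and products are disjoint.
    """
    rng = np.random.default_rng(config.seed)
    compounds = [f"cpd:CS{i:03d}" for i in range(config.n_compounds)]
    genes = [f"hsa:95{i:03d}" for i in range(config.n_genes)]

    # reaction spec: (substrates, products, genes, reversible)
    reactions = []
    for _ in range(config.n_reactions):
        # cap draws so there is always >=1 substrate and >=1 product,
        # disjoint by construction (requires n_compounds >= 2)
        n_sub = min(int(rng.integers(1, 3)), config.n_compounds - 1)
        n_prod = min(int(rng.integers(1, 3)), config.n_compounds - n_sub)
        picked = rng.choice(config.n_compounds, size=n_sub + n_prod, replace=False)
        subs = [compounds[i] for i in picked[:n_sub]]
        prods = [compounds[i] for i in picked[n_sub:]]
        n_gene = int(rng.integers(1, min(3, config.n_genes) + 1))
        gidx = rng.choice(config.n_genes, size=n_gene, replace=False)
        reactions.append(
            (
                subs,
                prods,
                [genes[i] for i in gidx],
                bool(rng.random() < config.p_reversible),
            )
        )
    relations = []
    for _ in range(config.n_relations):
        g1, g2 = rng.choice(config.n_genes, size=2, replace=False)
        relations.append((genes[g1], genes[g2]))

    pathways = []
    for p in range(config.n_pathways):
        pid = f"syn9{p:04d}"
        p_reactions = reactions[p :: config.n_pathways]
        p_relations = relations[p :: config.n_pathways]
        used_compounds = sorted(
            {c for subs, prods, _, _ in p_reactions for c in subs + prods}
        )
        used_genes = sorted(
            {g for _, _, gs, _ in p_reactions for g in gs}
            | {g for pair in p_relations for g in pair}
        )
        entry_id = {}
        lines = [f'<pathway name="path:{pid}" title="Random pathway {p}">']
        next_id = 1
        for c in used_compounds:
            entry_id[c] = next_id
            lines.append(
                f'<entry id="{next_id}" name="{c}" type="compound">'
                f'<graphics name="{c.split(":")[1]}"/></entry>'
            )
            next_id += 1
        gene_reactions: dict[str, list[str]] = {g: [] for g in used_genes}
        for i, (_, _, gs, _) in enumerate(p_reactions):
            rname = f"rn:RR{p:02d}{i:03d}"
            for g in gs:
                gene_reactions[g].append(rname)
        for g in used_genes:
            entry_id[g] = next_id
            rattr = (
                f' reaction="{" ".join(gene_reactions[g])}"'
                if gene_reactions[g]
                else ""
            )
            lines.append(
                f'<entry id="{next_id}" name="{g}" type="gene"{rattr}>'
                f'<graphics name="{g.split(":")[1]}"/></entry>'
            )
            next_id += 1
        for g1, g2 in p_relations:
            lines.append(
                f'<relation entry1="{entry_id[g1]}" entry2="{entry_id[g2]}" '
                'type="PPrel"><subtype name="activation"/></relation>'
            )
        for i, (subs, prods, _, rev) in enumerate(p_reactions):
            rname = f"rn:RR{p:02d}{i:03d}"
            rtype = "reversible" if rev else "irreversible"
            lines.append(f'<reaction id="{next_id}" name="{rname}" type="{rtype}">')
            next_id += 1
            for c in subs:
                lines.append(f'<substrate id="{entry_id[c]}" name="{c}"/>')
            for c in prods:
                lines.append(f'<product id="{entry_id[c]}" name="{c}"/>')
            lines.append("</reaction>")
        lines.append("</pathway>")
        pathways.append(parse_kgml("\n".join(lines)))
    return pathways


def random_annotations(
    network: MetaboNetwork, config: SynthConfig, tissue: str = "hepatocytes"
) -> AnnotationTables:
    """Random annotation tables with controlled coverage fractions.

    Exactly ``floor(frac_expressed * n_genes)`` genes get positive
    expression values (the rest 0); ``floor(frac_prognostic * n_genes)``
    genes get log-rank p-values below 0.001 (the rest well above);
    ``floor(frac_urine * n_metabolites)`` metabolites get urine records.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(network.gene_ids)
    metabolites = sorted(network.metabolite_ids)

    n_expr = int(np.floor(config.frac_expressed * len(genes)))
    expressed = set(rng.permutation(genes)[:n_expr]) if genes else set()
    expression = pd.DataFrame(
        {
            "gene_id": genes,
            "tissue": tissue,
            "value": [
                float(np.round(rng.uniform(1.0, 20.0), 3)) if g in expressed else 0.0
                for g in genes
            ],
        }
    )

    n_prog = int(np.floor(config.frac_prognostic * len(genes)))
    prognostic = set(rng.permutation(genes)[:n_prog]) if genes else set()
    prognosis = pd.DataFrame(
        {
            "gene_id": genes,
            "direction": [
                str(rng.choice(["favorable", "unfavorable"])) for _ in genes
            ],
            "logrank_p": [
                float(10.0 ** rng.uniform(-11, -4))
                if g in prognostic
                else float(np.round(rng.uniform(0.01, 0.9), 6))
                for g in genes
            ],
        }
    )

    n_urine = int(np.floor(config.frac_urine * len(metabolites)))
    with_urine = sorted(rng.permutation(metabolites)[:n_urine]) if metabolites else []
    biofluid = pd.DataFrame(
        {
            "metabolite_id": with_urine,
            "in_normal_urine": [bool(rng.random() < 0.7) for _ in with_urine],
            "in_abnormal_urine": [bool(rng.random() < 0.7) for _ in with_urine],
        }
    )
    return AnnotationTables(
        expression=expression, prognosis=prognosis, biofluid=biofluid
    )
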