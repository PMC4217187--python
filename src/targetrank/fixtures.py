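"""Packaged evaluation fixture: the published eQTL validation table.

Eighteen (SNP, disease, target gene) instances with their channel scores
(genomic distance GD in bp, HiC contact log-ratio, literature t score) and
fractional ranks (rD, rHiC, rL, hybrid rHy) over a universe of ``Total``
same-chromosome genes more than 500 kbp from the SNP. ``nan`` in the Lit
column means no literature evidence was found for the pair. Values are
stored at their printed precision.

Two of the SNPs (rs2029166 and rs7296239) lie within 2 kbp of each other and
received identical spatial and literature scores; merging them leaves 17
evaluation instances.
"""

from __future__ import annotations

import io
import math

import pandas as pd

from .benchmark import BenchmarkCase, EqtlPair

TABLE2_TSV = """\
pubmed_id\trsid\tdisease\tchrom\tlocation\tgene\tgene_id\tgene_window\teqtl_p\tGD\tHiC\tLit\trD\trHiC\trL\trHy\tTotal
21995493\trs652625\tCarcinoma, NSC Lung\tchr1\t12147937\tMTOR\t2475\tchr1:11M-12M\t3.94E-05\t902741\t6.84\t1.17\t0.0091\t0.0046\t0.0282\t0.0012\t2408
20937265\trs344781\tCarcinoma, NSC Lung\tchr19\t48866627\tPSG11\t5680\tchr19:48M-49M\t1.96E-05\t644155\t7.16\tnan\t0.0031\t0.0006\t0.2842\t0.0013\t1594
21761413\trs344781\tEndometrial Neoplasms\tchr19\t48866627\tPSG11\t5680\tchr19:48M-49M\t1.96E-05\t644155\t7.16\tnan\t0.0031\t0.0006\t0.2748\t0.0013\t1594
20937265\trs344781\tLung Neoplasms\tchr19\t48866627\tPSG11\t5680\tchr19:48M-49M\t1.96E-05\t644155\t7.16\tnan\t0.0031\t0.0006\t0.2992\t0.0013\t1594
19760037\trs7187167\tBreast Neoplasms\tchr16\t1289209\tWDR24\t84219\tchr16:0-1M\t2.73E-05\t608807\t7.21\tnan\t0.0156\t0.0021\t0.7419\t0.0042\t961
21995493\trs652625\tLung Neoplasms\tchr1\t12147937\tMTOR\t2475\tchr1:11M-12M\t3.94E-05\t902741\t6.84\t-5.59\t0.0091\t0.0046\t0.2263\t0.0046\t2408
23059779\trs12983047\tCarcinoma, Squamous Cell\tchr19\t46526338\tCIC\t23152\tchr19:47M-48M\t0.00036\t954318\t7.15\t1.42\t0.0218\t0.0230\t0.0131\t0.0075\t1607
19358266\trs7187167\tLymphatic Metastasis\tchr16\t1289209\tWDR24\t84219\tchr16:0-1M\t2.73E-05\t608807\t7.21\tnan\t0.0156\t0.0021\t0.7034\t0.0083\t961
23059779\trs12983047\tAdenocarcinoma\tchr19\t46526338\tCIC\t23152\tchr19:47M-48M\t0.00036\t954318\t7.15\t0.33\t0.0218\t0.0230\t0.0492\t0.0137\t1607
23059779\trs12983047\tLung Neoplasms\tchr19\t46526338\tCIC\t23152\tchr19:47M-48M\t0.00036\t954318\t7.15\t-0.61\t0.0218\t0.0230\t0.0834\t0.0168\t1607
22267197\trs2823093\tBreast Neoplasms\tchr21\t15442702\tUSP25\t29761\tchr21:16M-17M\t0.00010\t581512\t6.57\t-1.75\t0.0101\t0.0709\t0.1723\t0.0169\t296
22344756\trs3213182\tCarcinoma, Squamous Cell\tchr20\t31726893\tITCH\t83737\tchr20:32M-33M\t0.00021\t687808\t6.95\t-5.09\t0.0142\t0.0236\t0.2079\t0.0173\t635
23059779\trs12983047\tCarcinoma, NSC Lung\tchr19\t46526338\tCIC\t23152\tchr19:47M-48M\t0.00036\t954318\t7.15\t-2.16\t0.0218\t0.0230\t0.1176\t0.0243\t1607
21427733\trs2029166\tBreast Neoplasms\tchr12\t52876365\tAAAS\t8086\tchr12:52M-53M\t7.79E-05\t874685\t6.40\t-2.42\t0.0131\t0.0533\t0.2238\t0.0262\t1144
21427733\trs7296239\tBreast Neoplasms\tchr12\t52877970\tAAAS\t8086\tchr12:52M-53M\t0.00011\t876290\t6.40\t-2.42\t0.0131\t0.0533\t0.2238\t0.0262\t1144
22344756\trs3213182\tHead and Neck Neoplasms\tchr20\t31726893\tITCH\t83737\tchr20:32M-33M\t0.00021\t687808\t6.95\tnan\t0.0142\t0.0236\t0.7858\t0.0283\t635
21733090\trs7096206\tCarcinoma, Hepatocellular\tchr10\t54201690\tCHUK\t1147\tchr10:101M-102M\t1.43E-06\t47777644\t2.00\t-1.08\t0.6705\t0.9153\t0.1695\t0.5931\t956
21733090\trs7096206\tLiver Neoplasms\tchr10\t54201690\tCHUK\t1147\tchr10:101M-102M\t1.43E-06\t47777644\t2.00\t-4.22\t0.6705\t0.9153\t0.2029\t0.6234\t956
"""


def table2_frame() -> pd.DataFrame:
    """The fixture as a DataFrame, one row per published instance."""
    return pd.read_csv(
        io.StringIO(TABLE2_TSV), sep="\t",
        dtype={"gene_id": str, "pubmed_id": str},
    )


def table2_fixture() -> list[BenchmarkCase]:
    """The fixture as benchmark cases (Lit ``nan`` becomes the undefined marker)."""
    cases = []
    for row in table2_frame().itertuples(index=False):
        cases.append(BenchmarkCase(
            rsid=row.rsid,
            disease=row.disease,
            gene_id=row.gene_id,
            symbol=row.gene,
            snp_pos=int(row.location),
            hic_log_ratio=float(row.HiC),
            lit_t=None if math.isnan(row.Lit) else float(row.Lit),
            rank_gen_dist=float(row.rD),
            rank_spatial=float(row.rHiC),
            rank_literature=float(row.rL),
            rank_hybrid=float(row.rHy),
            universe_size=int(row.Total),
        ))
    return cases


def table2_gold() -> list[EqtlPair]:
    """The unique (rsid, gene) eQTL pairs of the fixture with their p-values."""
    pairs: dict[tuple[str, str], EqtlPair] = {}
    for row in table2_frame().itertuples(index=False):
        key = (row.rsid, row.gene_id)
        if key not in pairs:
            pairs[key] = EqtlPair(row.rsid, row.gene_id, float(row.eqtl_p))
    return list(pairs.values())
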