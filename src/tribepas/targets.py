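"""Target-set algebra and expression filtering.

Combines HyperTRIBE target genes from two reader proteins (ECT2, ECT3)
with an external iCLIP list into permissive / stringent / non-target sets,
derives specificity classes from single- vs triple-mutant background
calls, overlays target sets onto single-cell marker lists, and applies the
expression filters and fold-change classification used for differential
expression summaries (the DE model fit itself is external).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import pandas as pd


@dataclass
class TargetSetCollection:
    expressed: frozenset
    ect2_ht: frozenset
    ect3_ht: frozenset
    ect2_iclip: frozenset
    permissive: frozenset = field(init=False)
    stringent: frozenset = field(init=False)
    non_target: frozenset = field(init=False)

    def __post_init__(self):
        if not self.expressed:
            raise ValueError("expressed gene set is empty")
        union = self.ect2_ht | self.ect3_ht | self.ect2_iclip
        self.permissive = frozenset(union & self.expressed)
        self.stringent = frozenset(
            ((self.ect2_ht | self.ect3_ht) & self.ect2_iclip) & self.expressed
        )
        self.non_target = frozenset(self.expressed - self.permissive)
        self.validate()

    def validate(self) -> None:
        assert self.stringent <= self.permissive
        assert not (self.non_target & self.permissive)
        assert self.non_target | self.permissive == self.expressed


def build_target_sets(ect2_ht, ect3_ht, ect2_iclip, expressed) -> TargetSetCollection:
    """Permissive = (ECT2-HT ∪ ECT3-HT ∪ ECT2-iCLIP) ∩ expressed;
    stringent = HT targets corroborated by iCLIP; non-target = the rest of
    the expressed genes."""
    return TargetSetCollection(
        expressed=frozenset(expressed),
        ect2_ht=frozenset(ect2_ht),
        ect3_ht=frozenset(ect3_ht),
        ect2_iclip=frozenset(ect2_iclip),
    )


@dataclass
class SpecificityClasses:
    ect2_strict: frozenset
    ect3_strict: frozenset
    ect2_acquired_by_ect3: frozenset  # ECT2-specific, gained by ECT3 in triple
    ect3_acquired_by_ect2: frozenset
    putative_ect4: frozenset

    def all_classes(self) -> dict:
        return {
            "ect2_strict": self.ect2_strict,
            "ect3_strict": self.ect3_strict,
            "ect2_acquired_by_ect3": self.ect2_acquired_by_ect3,
            "ect3_acquired_by_ect2": self.ect3_acquired_by_ect2,
            "putative_ect4": self.putative_ect4,
        }


def specificity_classes(ect2_single, ect2_triple, ect3_single, ect3_triple) -> SpecificityClasses:
    """Protein-specific target classes from single/triple background calls.

    Strictly specific: edited by one protein but not the other in single
    mutants (nor by the other in triple).  Acquired: a specific target of
    one protein gained by the other only in the triple background.
    Putative ECT4: edited by either protein only in the triple background.
    The classes are pairwise disjoint by construction.
    """
    e2s, e2t = frozenset(ect2_single), frozenset(ect2_triple)
    e3s, e3t = frozenset(ect3_single), frozenset(ect3_triple)
    return SpecificityClasses(
        ect2_strict=e2s - (e3s | e3t),
        ect3_strict=e3s - (e2s | e2t),
        ect2_acquired_by_ect3=(e2s - e3s) & e3t,
        ect3_acquired_by_ect2=(e3s - e2s) & e2t,
        putative_ect4=(e2t | e3t) - (e2s | e3s),
    )


def marker_target_proportion(markers_by_cluster: dict, targets) -> dict:
    """Per-cluster proportion of marker genes that are targets.

    Empty marker lists yield NaN for that cluster.
    """
    targets = set(targets)
    out = {}
    for cluster, markers in markers_by_cluster.items():
        markers = set(markers)
        out[cluster] = len(markers & targets) / len(markers) if markers else float("nan")
    return out


def filter_and_classify_expression(
    expr: pd.DataFrame,
    stats: pd.DataFrame,
    mode: str = "mrna",
    tpm_min: float = 1.0,
    total_min: float = 5.0,
    rpm_min: float = 1.0,
    fdr_max: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Expression filtering and up/down/unchanged classification.

    ``expr`` is genes x samples (TPM for mRNA mode, RPM for small-RNA
    mode); ``stats`` indexes genes with columns ``fold_change``
    (mutant over wild type) and ``padj`` from an external DE fit.

    mRNA mode keeps genes with >= 1 TPM in every sample and a total of at
    least 5 TPM; small-RNA mode drops genes below 1 RPM in all samples.
    Kept genes are classified up (FDR < 0.05 and FC > 1.5), down
    (FDR < 0.05 and FC < 1/1.5), unchanged otherwise, or untested when no
    statistics exist for them.  Small-RNA significance uses FDR <= 0.05.
    """
    if mode == "mrna":
        keep = (expr >= tpm_min).all(axis=1) & (expr.sum(axis=1) >= total_min)
        strict_fdr = True
    elif mode == "smallrna":
        keep = ~(expr < rpm_min).all(axis=1)
        strict_fdr = False
    else:
        raise ValueError("mode must be 'mrna' or 'smallrna'")
    kept = expr.loc[keep]
    rows = []
    for gene in kept.index:
        if gene not in stats.index or stats.loc[gene].isna().any():
            rows.append({"gene_id": gene, "class": "untested"})
            continue
        fc = float(stats.loc[gene, "fold_change"])
        padj = float(stats.loc[gene, "padj"])
        sig = padj < fdr_max if strict_fdr else padj <= fdr_max
        if sig and fc > fc_threshold:
            cls = "up"
        elif sig and fc < 1.0 / fc_threshold:
            cls = "down"
        else:
            cls = "unchanged"
        rows.append({"gene_id": gene, "class": cls})
    return pd.DataFrame(rows).set_index("gene_id")


def read_gene_list(path) -> frozenset:
    """One gene id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
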