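"""Early Partner Choice (EPC) index and replicate statistics.

The EPC index of a strain in a sample is the percentage of the sample's
assigned barcode reads that belong to that strain; per host genotype the
reported value is the mean over biological replicates (the study design
uses four), with reliability summarised by the coefficient of variation
CV% = 100 * sd / mean.  Strains never seen in any sample are removed
before analysis; rare-but-present strains are kept.  Host and strain
EPC profiles are compared by agglomerative hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .amplicon import CountTable


@dataclass
class EPCTable:
    """Per-sample EPC percentages plus replicate summaries.

    ``epc`` columns over detected strains sum to 100 for every sample
    with at least one assigned read; ``cv_percent`` is missing where the
    replicate mean is zero.
    """

    epc: pd.DataFrame           # strains x samples, percent
    epc_mean: pd.DataFrame      # strains x host genotypes
    cv_percent: pd.DataFrame    # strains x host genotypes
    detected: pd.Series         # bool per strain (pre-filter universe)


@dataclass
class ProfileClustering:
    host_linkage: np.ndarray
    strain_linkage: np.ndarray
    host_order: list[str]
    strain_order: list[str]
    metric: str
    method: str

    def host_newick(self) -> str:
        return _linkage_to_newick(self.host_linkage, self.host_labels)

    def strain_newick(self) -> str:
        return _linkage_to_newick(self.strain_linkage, self.strain_labels)

    # label lists in original (sorted) input order, set by cluster_profiles
    host_labels: list[str] = None
    strain_labels: list[str] = None


def compute_epc(count_table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample EPC matrix: ``100 * count / sample total``.

    Columns with zero total are all-missing and a warning names them.
    """
    counts = count_table.counts if isinstance(count_table, CountTable) else count_table
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"samples with zero assigned reads: {empty}",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        epc = 100.0 * counts / totals
    epc.loc[:, empty] = np.nan
    return epc


def summarize_replicates(epc: pd.DataFrame, sample_sheet: pd.DataFrame,
                         pooled_counts: pd.DataFrame | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate mean EPC and CV% per strain x host genotype.

    The mean is over replicate percentages, not pooled counts (the two
    differ under unequal depth; pass ``pooled_counts`` to get the pooled
    percentage instead).  CV uses the n-1 sample standard deviation and
    is missing where the mean is zero.  A host whose samples are all
    missing raises.
    """
    hosts = sample_sheet.set_index("sample_id")["host_genotype"]
    unknown = [s for s in epc.columns if s not in hosts.index]
    if unknown:
        raise ValueError(f"samples absent from the sample sheet: {unknown}")
    if pooled_counts is not None:
        grouped = pooled_counts.T.groupby(hosts.reindex(pooled_counts.columns)).sum().T
        mean = compute_epc(grouped)
    else:
        mean = epc.T.groupby(hosts.reindex(epc.columns)).mean().T
    bad = [h for h in mean.columns if mean[h].isna().all()]
    if bad:
        raise ValueError(f"conditions with zero usable replicates: {bad}")
    sd = epc.T.groupby(hosts.reindex(epc.columns)).std(ddof=1).T
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * sd / mean
    cv[mean == 0] = np.nan
    return mean, cv


def filter_undetected(count_table: CountTable | pd.DataFrame) -> pd.Series:
    """Boolean per strain: True iff at least one read in any sample.

    The filter operates on raw counts; a single read in a single sample
    keeps a strain in the analysis.
    """
    counts = count_table.counts if isinstance(count_table, CountTable) else count_table
    return counts.sum(axis=1) > 0


def epc_table(count_table: CountTable | pd.DataFrame,
              sample_sheet: pd.DataFrame) -> EPCTable:
    """Full EPC summary: detection filter, per-sample EPC over detected
    strains, replicate means and CV%."""
    counts = count_table.counts if isinstance(count_table, CountTable) else count_table
    detected = filter_undetected(counts)
    epc = compute_epc(counts.loc[detected[detected].index])
    mean, cv = summarize_replicates(epc, sample_sheet)
    return EPCTable(epc=epc, epc_mean=mean, cv_percent=cv, detected=detected)


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def fmt(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = fmt(node.get_left(), node.dist)
        right = fmt(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return fmt(tree, tree.dist) + ";"


def cluster_profiles(epc_mean: pd.DataFrame, metric: str = "euclidean",
                     method: str = "complete") -> ProfileClustering:
    """Agglomerative clustering of hosts (columns) and strains (rows).

    Input order does not matter: labels are sorted before linkage so tied
    merges resolve identically for any ordering.  Missing cells raise.
    """
    if epc_mean.isna().any().any():
        raise ValueError("missing cells in EPC matrix: rerun without "
                         "conditions that have no usable replicates")
    if epc_mean.shape[0] < 2 or epc_mean.shape[1] < 2:
        raise ValueError("need at least 2 strains and 2 hosts")
    mat = epc_mean.sort_index(axis=0).sort_index(axis=1)
    strain_labels = list(mat.index)
    host_labels = list(mat.columns)
    strain_link = hierarchy.linkage(pdist(mat.to_numpy(), metric=metric),
                                    method=method)
    host_link = hierarchy.linkage(pdist(mat.to_numpy().T, metric=metric),
                                  method=method)
    strain_order = [strain_labels[i] for i in hierarchy.leaves_list(strain_link)]
    host_order = [host_labels[i] for i in hierarchy.leaves_list(host_link)]
    out = ProfileClustering(host_linkage=host_link, strain_linkage=strain_link,
                            host_order=host_order, strain_order=strain_order,
                            metric=metric, method=method)
    out.host_labels = host_labels
    out.strain_labels = strain_labels
    return out


def cut_host_groups(clustering: ProfileClustering, n_groups: int) -> dict[str, int]:
    """Flat host groups from the host dendrogram cut at ``n_groups``."""
    assignments = hierarchy.fcluster(clustering.host_linkage, t=n_groups,
                                     criterion="maxclust")
    return dict(zip(clustering.host_labels, (int(a) for a in assignments)))
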