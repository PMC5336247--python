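"""Chemical-specific publication profiles and data-gap matrices.

A publication profile summarises, for one chemical, how the abstracts the
classifier judged relevant distribute over the taxonomy: per node the count
of positively classified documents and its percentage of all relevant
documents (those predicted positive for at least one node).  Because the
classification is multi-label, percentages do not sum to 100.  Profile
matrices stack several chemicals side by side and flag node/chemical cells
with zero documents — candidate data gaps in the published literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classify import PredictionSet
from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "PublicationProfile",
    "publication_profile",
    "compare_profiles",
    "plot_profile",
]


@dataclass
class PublicationProfile:
    """Per-node publication counts for one chemical."""

    label: str
    taxonomy: Taxonomy
    total_relevant: int
    node_counts: dict[str, int]

    def percent(self, node: str) -> float:
        """Node count as a percentage of all relevant documents (0 when
        no document was relevant at all)."""
        node = self.taxonomy.resolve(node)
        if self.total_relevant == 0:
            return 0.0
        return 100.0 * self.node_counts.get(node, 0) / self.total_relevant

    @property
    def degenerate(self) -> bool:
        return self.total_relevant == 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": node,
                "count": self.node_counts.get(node, 0),
                "percent": self.percent(node),
            }
            for node in self.taxonomy.node_names
        ]
        return pd.DataFrame(rows).set_index("node")


def publication_profile(
    pred: PredictionSet | Mapping[str, set[str]],
    taxonomy: Taxonomy | None = None,
    label: str = "",
) -> PublicationProfile:
    """Build one chemical's profile from a prediction set.

    A document is *relevant* when it is predicted positive for at least
    one node (branch-root-only positives count as relevant); each document
    is counted once per node it is labelled with.
    """
    taxonomy = taxonomy or default_taxonomy()
    pred_labels = pred.labels if isinstance(pred, PredictionSet) else pred
    node_counts: dict[str, int] = {}
    total_relevant = 0
    for labels in pred_labels.values():
        if not labels:
            continue
        total_relevant += 1
        for node in labels:
            slug = taxonomy.resolve(node)
            node_counts[slug] = node_counts.get(slug, 0) + 1
    return PublicationProfile(
        label=label,
        taxonomy=taxonomy,
        total_relevant=total_relevant,
        node_counts=node_counts,
    )


def compare_profiles(
    profiles: Sequence[PublicationProfile],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stack profiles into node x chemical matrices.

    Returns ``(counts, percents, gaps)`` DataFrames with rows in taxonomy
    traversal order and one column per chemical; ``gaps`` is a boolean
    data-gap flag for zero-count cells.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    first = profiles[0].taxonomy
    for p in profiles[1:]:
        if p.taxonomy.node_names != first.node_names:
            raise ValueError("profiles span different taxonomies")
    nodes = list(first.node_names)
    counts = pd.DataFrame(
        {
            p.label: [p.node_counts.get(n, 0) for n in nodes]
            for p in profiles
        },
        index=nodes,
    )
    percents = pd.DataFrame(
        {p.label: [p.percent(n) for n in nodes] for p in profiles},
        index=nodes,
    )
    gaps = counts == 0
    return counts, percents, gaps


def plot_profile(profile: PublicationProfile, path: str) -> None:
    """Bar-chart export (node on x, percent of relevant documents on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nodes = list(profile.taxonomy.node_names)
    values = [profile.percent(n) for n in nodes]
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(range(len(nodes)), values)
    ax.set_xticks(range(len(nodes)))
    ax.set_xticklabels(
        [profile.taxonomy.display(n) for n in nodes],
        rotation=90,
        fontsize=7,
    )
    ax.set_ylabel("% of relevant abstracts")
    ax.set_title(
        f"{profile.label} (n = {profile.total_relevant} relevant abstracts)"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
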