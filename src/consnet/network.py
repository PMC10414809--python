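"""Two-layer constructive network assembly.

A constructive network collates the two fitted matrices into one signed,
weighted multilayer graph: an *alpha layer* linking species to
environment/microhabitat nodes, and a *beta layer* linking species
pairs.  Positive alpha means a species is associated with (thrives in)
a microhabitat or responds positively to a factor; negative alpha means
avoidance.  Beta links are undirected — one link per unordered species
pair — and keep the raw fitted coefficient as their weight.

Nurse-plant systems are represented with the nurse canopy and the open
ground as two environment nodes, so "facilitation by the nurse" appears
as a positive alpha link from the nurse microhabitat to a subordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mrf import MarkovNetworkParams
from .null_models import AlphaScreenResult, NullScreenResult

__all__ = ["AlphaLink", "BetaLink", "ConstructiveNetwork", "build_network", "network_summary"]


@dataclass(frozen=True)
class AlphaLink:
    species: str
    factor: str
    weight: float
    sign: int
    q_value: float = float("nan")


@dataclass(frozen=True)
class BetaLink:
    species_i: str  # canonical: species_i precedes species_j in species order
    species_j: str
    weight: float
    sign: int
    q_value: float = float("nan")


@dataclass
class ConstructiveNetwork:
    """Signed two-layer network of species, environment factors and links."""

    species_nodes: list
    environment_nodes: list
    alpha_links: list = field(default_factory=list)
    beta_links: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_networkx(self):
        """Single multilayer graph: node attribute ``type`` in
        {species, environment}, edge attribute ``layer`` in {alpha, beta}."""
        import networkx as nx

        g = nx.Graph()
        for s in self.species_nodes:
            g.add_node(s, type="species", name=s)
        for e in self.environment_nodes:
            g.add_node(e, type="environment", name=e)
        for link in self.alpha_links:
            g.add_edge(
                link.factor, link.species, layer="alpha",
                weight=float(link.weight), sign=int(link.sign),
                q_value=float(link.q_value),
            )
        for link in self.beta_links:
            g.add_edge(
                link.species_i, link.species_j, layer="beta",
                weight=float(link.weight), sign=int(link.sign),
                q_value=float(link.q_value),
            )
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def to_edge_frame(self):
        """Edge list; alpha links are rendered factor -> species."""
        import pandas as pd

        rows = [
            {"source": l.factor, "target": l.species, "layer": "alpha",
             "weight": l.weight, "sign": l.sign, "q_value": l.q_value}
            for l in self.alpha_links
        ] + [
            {"source": l.species_i, "target": l.species_j, "layer": "beta",
             "weight": l.weight, "sign": l.sign, "q_value": l.q_value}
            for l in self.beta_links
        ]
        return pd.DataFrame(rows, columns=["source", "target", "layer", "weight", "sign", "q_value"])

    def to_edge_tsv(self, path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)


def build_network(
    params: MarkovNetworkParams,
    screen: NullScreenResult | None = None,
    alpha_screen: AlphaScreenResult | None = None,
    fdr: float = 0.05,
    min_weight: float = 0.0,
) -> ConstructiveNetwork:
    """Assemble the constructive network from (screened) parameters.

    A beta link for pair (i, j) is kept when |beta_ij| >= ``min_weight``
    and, if a screen is given, q_ij < ``fdr`` — significance and effect
    size are distinct filters and a link must pass both.  Alpha links
    are filtered the same way against ``alpha_screen``.  Zero-weight and
    non-finite parameters never become links; each link's sign is the
    sign of its weight.
    """
    if screen is not None and screen.species_names != params.species_names:
        raise ValueError("screen species labels do not match params")
    if alpha_screen is not None and (
        alpha_screen.species_names != params.species_names
        or alpha_screen.factor_names != params.factor_names
    ):
        raise ValueError("alpha screen labels do not match params")

    species = list(params.species_names)
    factors = list(params.factor_names)
    alpha_links: list[AlphaLink] = []
    beta_links: list[BetaLink] = []

    sig_a = alpha_screen.significant(fdr) if alpha_screen is not None else None
    for i, s in enumerate(species):
        for f, fac in enumerate(factors):
            w = params.alpha[i, f]
            if not np.isfinite(w) or w == 0.0 or abs(w) < min_weight:
                continue
            if sig_a is not None and not sig_a[i, f]:
                continue
            q = float(alpha_screen.q_values[i, f]) if alpha_screen is not None else float("nan")
            alpha_links.append(AlphaLink(s, fac, float(w), int(np.sign(w)), q))

    sig_b = screen.significant(fdr) if screen is not None else None
    iu, ju = np.triu_indices(len(species), k=1)
    for i, j in zip(iu, ju):
        w = params.beta[i, j]
        if not np.isfinite(w) or w == 0.0 or abs(w) < min_weight:
            continue
        if sig_b is not None and not sig_b[i, j]:
            continue
        q = float(screen.q_values[i, j]) if screen is not None else float("nan")
        beta_links.append(BetaLink(species[i], species[j], float(w), int(np.sign(w)), q))

    provenance = {
        "fdr": fdr,
        "min_weight": min_weight,
        "beta_screen": None if screen is None else {
            "method": screen.method, "n_permutations": screen.n_permutations,
            "seed": screen.seed, "unreliable": screen.unreliable,
        },
        "alpha_screen": None if alpha_screen is None else {
            "method": alpha_screen.method, "n_permutations": alpha_screen.n_permutations,
            "seed": alpha_screen.seed, "unreliable": alpha_screen.unreliable,
        },
    }
    return ConstructiveNetwork(species, factors, alpha_links, beta_links, provenance)


def network_summary(net: ConstructiveNetwork) -> dict:
    """Per-layer link counts, signs, degrees and connectance."""
    S = len(net.species_nodes)
    F = len(net.environment_nodes)
    a_pos = sum(1 for l in net.alpha_links if l.sign > 0)
    a_neg = len(net.alpha_links) - a_pos
    b_pos = sum(1 for l in net.beta_links if l.sign > 0)
    b_neg = len(net.beta_links) - b_pos
    degree = {s: 0 for s in net.species_nodes}
    for l in net.alpha_links:
        degree[l.species] += 1
    for l in net.beta_links:
        degree[l.species_i] += 1
        degree[l.species_j] += 1
    n_possible_a = S * F
    n_possible_b = S * (S - 1) // 2
    n_links = len(net.alpha_links) + len(net.beta_links)
    return {
        "n_alpha_links": len(net.alpha_links),
        "n_beta_links": len(net.beta_links),
        "alpha_positive": a_pos,
        "alpha_negative": a_neg,
        "beta_positive": b_pos,
        "beta_negative": b_neg,
        "alpha_connectance": len(net.alpha_links) / n_possible_a if n_possible_a else 0.0,
        "beta_connectance": len(net.beta_links) / n_possible_b if n_possible_b else 0.0,
        "positive_fraction": (a_pos + b_pos) / n_links if n_links else 0.0,
        "species_degree": degree,
    }


def plot_network(net: ConstructiveNetwork, ax=None):
    """Minimal two-layer plot: environment nodes as squares on top,
    species below; blue = positive link, red = negative."""
    import matplotlib.pyplot as plt
    import networkx as nx

    g = net.to_networkx()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    pos = {}
    for k, e in enumerate(net.environment_nodes):
        pos[e] = (k - (len(net.environment_nodes) - 1) / 2, 1.0)
    for k, s in enumerate(net.species_nodes):
        pos[s] = (k - (len(net.species_nodes) - 1) / 2, 0.0)
    colors = ["tab:blue" if d["sign"] > 0 else "tab:red" for _, _, d in g.edges(data=True)]
    widths = [1 + 2 * abs(d["weight"]) for _, _, d in g.edges(data=True)]
    nx.draw_networkx_edges(g, pos, ax=ax, edge_color=colors, width=widths)
    nx.draw_networkx_nodes(g, pos, nodelist=net.environment_nodes, node_shape="s",
                           node_color="lightgray", ax=ax)
    nx.draw_networkx_nodes(g, pos, nodelist=net.species_nodes, node_color="lightgreen", ax=ax)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    ax.set_axis_off()
    return ax
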