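"""Build, annotate, lay out and export a two-step interaction network.

Extracts the nodes within distance 2 of a query protein, computes clustering
coefficients and expression correlations, lays the subnetwork out in 3D and
writes it in XYZ chemical format.
"""

import io

from phytodesk import (
    clustering_coefficient,
    export_xyz,
    layout_3d,
    load_edges,
    render_spec,
    two_step_subnetwork,
)
from phytodesk.netview import annotate_network, read_expression_tsv, shell_symbols
from phytodesk.fixtures import make_network_fixture

fix = make_network_fixture(seed=1, n=30, p=0.1, planted_triangles=2)
graph = load_edges(io.StringIO(fix.edges_tsv))
sub = two_step_subnetwork(graph, fix.query, depth=2)
print(f"two-step network of {fix.query}: "
      f"{sub.number_of_nodes()} nodes, {sub.number_of_edges()} edges")
print(f"query clustering coefficient: "
      f"{clustering_coefficient(sub, fix.query):.2f}")

expression = read_expression_tsv(io.StringIO(fix.expression_tsv))
annotate_network(sub, fix.query, expression=expression)

layout = layout_3d(sub, seed=42)
xyz = export_xyz(layout, shell_symbols(sub, fix.query),
                 comment=f"query={fix.query} seed=42")
print()
print("\n".join(xyz.splitlines()[:6]))
print("...")
# line 1 is the node count; each atom line is "SYMBOL x y z" with the query
# as N, direct neighbors as C and second-shell nodes as O.

spec = render_spec(sub, fix.query, size_metric="clustering")
print()
print(spec.head().to_string(index=False))
# node sizes scale linearly with the chosen metric; shell is the BFS distance.
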