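"""Two-stage clustering: syn/anti bitstrings, then eRMSD max-weight cliques.

Generates a three-state toy ensemble and clusters it.  Each printed row
is one cluster: its population (sum of member weights), the syn/anti
bitstring shared by every member, and the member count.  Snapshots in
one cluster are guaranteed pairwise eRMSD < 0.7 with identical
bitstring, so each cluster is a structurally homogeneous sub-state.
"""

from noeme import cluster_ensemble
from noeme.clustering import cluster_report
from noeme.synthetic import StateSpec, generate_toy_ensemble

states = [
    StateSpec("A", 0.5, syn_residues=(2,)),
    StateSpec("B", 0.3, syn_residues=(5,)),
    StateSpec("C", 0.2, syn_residues=(3, 6)),
]
ensemble, labels = generate_toy_ensemble(7, states, 120, seed=5)

clusters = cluster_ensemble(ensemble)
print(cluster_report(clusters).to_string(index=False))
print()
for c in clusters:
    true = {labels[m] for m in c.members}
    print(f"cluster {c.cluster_id} corresponds to planted state(s) {sorted(true)}")
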