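"""Flow roles and organigrams on a planted reference/mediator/listener
network.

Walk-count feature vectors (incoming and outgoing walks of all lengths)
are compared by cosine similarity, condensed into a role-similarity graph
with the relaxed minimum spanning tree, and clustered with the Markov
Stability sweep.  The three planted roles are recovered without fixing
their number in advance; interest communities are then profiled by their
role mix and clustered into organigram types.
"""
import numpy as np
from sklearn.metrics import adjusted_rand_score

import flowscope as fs

net, truth = fs.generate_role_planted(fs.PlantedRoleSpec(seed=1))
print(f"planted roles: 20 references / 20 mediators / 60 listeners, "
      f"{net.n_edges} follower edges")

Xf = fs.build_feature_matrix(net)
Y = fs.cosine_similarity(Xf)
print(f"feature matrix: K_max={Xf.k_max} walk lengths, alpha={Xf.alpha:.3g}")

rsg = fs.rmst(fs.similarity_to_distance(Y), gamma=fs.DEFAULT_ROLE_GAMMA,
              similarity=Y)
detected = fs.detect_roles(rsg, net, seed=11)
ari = adjusted_rand_score(
    truth.labels, detected.as_partition().aligned_labels(truth.node_labels)
)
print(f"detected {detected.n_roles} roles on plateau t in "
      f"[{detected.window[0]:.3g}, {detected.window[1]:.3g}]; "
      f"ARI to planted = {ari:.2f}")

# roles are ordered by in-strength; profile their flow patterns
prof = fs.role_flow_profiles(detected, Xf)
for r in range(detected.n_roles):
    sub = prof[(prof["role"] == r) & (prof["length"] == 1)]
    means = dict(zip(sub["direction"], sub["mean_log1p"]))
    print(f"  role {r}: mean log1p walk counts at length 1 — "
          f"in {means['in']:.2f}, out {means['out']:.2f}")

# role mixes of the planted communities, clustered into organigram types
part = fs.Partition(net.node_labels,
                    np.repeat([0, 1, 2, 3], [20, 20, 30, 30]))
mix = fs.role_mix(part, detected)
org = fs.cluster_role_mixes(mix, k="auto", seed=5)
print(f"\n{part.k} communities fall into {org.k} organigram types "
      f"(role-mix k-means):")
for c, (frac, lab) in enumerate(zip(mix.fractions, org.labels)):
    print(f"  community {c}: mix={np.round(frac, 2)}  type={lab}")
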