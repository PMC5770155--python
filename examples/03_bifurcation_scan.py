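"""Locate the codimension-one bifurcations of the reference circuit.

Evaluates the analytic necessary conditions on the weights, then scans
the inhibitory stimulus at I_E = 1 (crossing a Hopf point and a
branching point) and the excitatory stimulus at I_I = -35 (crossing two
folds).
"""

import ratecorr as rc

net = rc.default_network()
noise = rc.default_noise()

q_sn, ok_sn = rc.saddle_node_condition(net)
q_bp, ok_bp = rc.branching_condition(net)
h = rc.hopf_condition(net)
print("necessary conditions on the weights:")
print(f"  saddle-node     : quantity = {q_sn:.4f} (> 1: {ok_sn})")
print(f"  Andronov-Hopf   : discriminant = {h.discriminant:.1f}, z = {h.z:.4f}, satisfied: {h.satisfied}")
print(f"  branching point : quantity = {q_bp:.4f} (> 1: {ok_bp})")

print("\nscan I_I in [-30, 5] at I_E = 1:")
for p in rc.locate_on_segment("I_I", (-30.0, 5.0), 1.0, net, noise, step=0.01):
    print(f"  {p.kind:16s} I_I = {p.location:+9.4f}   [{p.eigen_signature}]")

print("\nscan I_E in [5, 20] at I_I = -35:")
for p in rc.locate_on_segment("I_E", (5.0, 20.0), -35.0, net, noise, step=0.01):
    tag = "stable branch" if p.stable_side else "unstable branch"
    print(f"  {p.kind:16s} I_E = {p.location:+9.4f}   ({tag})")
print(
    "-> each bifurcation kind is signalled by a different eigenvalue\n"
    "   crossing: a real collective eigenvalue (fold), the conjugate\n"
    "   collective pair (Hopf), or the inhibitory intra-population\n"
    "   eigenvalue (branching point / symmetry breaking)."
)
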