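"""Why edge orientation matters: the flow-trap benchmark.

The flow-trap generator plants two blocks whose edges circulate within a
block (directed flow is retained) while the symmetrized network is a
homogeneous random graph: within- and between-block pair probabilities are
equal, so no density contrast survives when orientation is ignored.  The
directed sweep recovers the blocks far better than the sweep on the
symmetrized network — the signal is purely directional.
"""
import flowscope as fs

spec = fs.PlantedFlowSpec(block_sizes=(20, 20), p_in=0.35, p_out=0.35,
                          orientation="cyclic-within-block", seed=1)
net, planted = fs.generate_flow_trap(spec)
sym = fs.symmetrize(net)
deg = sym.in_strength + sym.out_strength
print(f"flow trap: N={net.N}, {net.n_edges} edges; symmetrized degree "
      f"CV = {deg.std() / deg.mean():.3f} (homogeneous)")

times = fs.default_time_grid(n=24)
directed = fs.stability_sweep(net, times=times, n_runs=4, seed=3)
undirected = fs.stability_sweep(sym, times=times, n_runs=4, seed=3)

d = min(fs.variation_of_information(p, planted) for p in directed.partitions)
u = min(fs.variation_of_information(p, planted) for p in undirected.partitions)
print(f"best VI to planted blocks, directed sweep:    {d:.3f}")
print(f"best VI to planted blocks, symmetrized sweep: {u:.3f}")
print("lower is better; the directed analysis sees structure that "
      "symmetrization destroys.")
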