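"""Multi-resolution interest communities on a planted directed block model.

Generates a 4-block directed SBM, sweeps Markov Stability across two
decades of Markov time, and reports the robust plateaus.  Small Markov
times resolve fine flow structure (here: one community per node); the
planted four blocks appear as a long plateau at intermediate-to-long times.
"""
import flowscope as fs

net, planted = fs.generate_directed_sbm(fs.PlantedFlowSpec(seed=1))
print(f"network: N={net.N}, {net.n_edges} directed edges, "
      f"4 planted blocks of 25")

seq = fs.stability_sweep(net, times=fs.default_time_grid(n=24), n_runs=4,
                         seed=7)
print("\n t        communities   stability r    restart VI")
for t, k, r, vi in zip(seq.times, seq.k, seq.r, seq.vi_runs):
    print(f" {t:8.3f}  {k:11d}   {r:11.4f}    {vi:.4f}")

print("\nrobust plateaus (window, k, VI to planted blocks):")
for (t0, t1), part in fs.select_robust_partitions(seq):
    vi = fs.variation_of_information(part, planted)
    print(f"  t in [{t0:.3g}, {t1:.3g}]  k={part.k}  VI={vi:.4f}")
print("VI = 0 means the plateau partition equals the planted blocks.")
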