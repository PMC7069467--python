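"""Run every pipeline stage on a small simulated study.

Equivalent to `dynconn run-all` with a reduced problem size: simulated
cohort, preprocessed epochs, ERP statistics, per-subject time-varying
networks, MCS-vs-UWS difference networks at the snapshot latencies, graph
properties and the CRS-R association -- all written under ./dynconn_demo."""

from dynconn import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="dynconn_demo", seed=11, n_per_cell=4,
                     n_standard=20, n_deviant=15)
bundle = run_pipeline(cfg)
print("outputs in", bundle.out_dir)
print("retained difference-network edges per snapshot latency:")
for d in bundle.difference_networks:
    frontoparietal = [(e.source, e.sink) for e in d.edges
                      if e.source == "Fz" and e.sink == "Pz"]
    print(f"  {d.time_ms:6.0f} ms: {len(d.edges):2d} edges"
          + ("  (includes planted Fz->Pz)" if frontoparietal else ""))
print(bundle.associations.to_string(index=False))
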