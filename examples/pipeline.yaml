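# Declarative pipeline: simulate a dilution series, detect peaks in each
# replicate, align them, and quantify on common ions.
# Run with:  gcmskit run examples/pipeline.yaml
seed: 1
out_dir: scratch/pipeline_out
stages:
  - stage: simulate
    design: dilution
    replicates: 4
  - stage: detect
    preset: mix
    noise_floor: 100
  - stage: align
    D: 2.5
    gap: 0.30
    min_peaks: 1
  - stage: quantify
    n: 5
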