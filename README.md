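# dinotad

Topological-domain analysis for dinoflagellate-style genomes: Hi-C contact-map
balancing, insulation-based domain calling, gene-array orientation analysis,
and transcription-inhibition decompaction metrics — with a fully seeded
synthetic-data generator so every stage is testable against planted truth.

## The problem

Dinoflagellate genomes are organized into very long unidirectional *tandem
gene arrays*. Hi-C maps of such genomes resolve into large self-interacting
contact domains ("dinoTADs") whose boundaries coincide with **convergent**
array junctions — points where a forward-transcribed array meets a
reverse-transcribed one head-on — and which lose insulation when
transcription is chemically inhibited, consistent with transcription-induced
supercoiling as the folding force. This package implements the computational
chain needed to make and quantify those observations:

1. **Contact maps** (`dinotad.contact`): binned symmetric cis matrices with
   masking, Knight–Ruiz (KR) balancing (`w_i c_ij w_j` with unit row sums),
   cross-sample depth matching, distance-decay expectation `E[c | d] ∝ d^-α`,
   and observed/expected transforms.
2. **Domain calling** (`dinotad.domains`): multi-window TAD separation score
   — per bin edge *i* and window *w*, the mean balanced signal of the diamond
   `[i−w, i) × [i, i+w)`, z-scored per chromosome and averaged over windows —
   with boundaries at significant, prominent local minima under
   Benjamini–Hochberg FDR control.
3. **Transcription tracks** (`dinotad.transcripts`): strand inference for
   unstranded assemblies from splice-site dinucleotides (GT..AG ⇒ `+`,
   CT..AC ⇒ `−`), an ORF-length filter (< 60 aa dropped), per-bp summed-TPM
   strand tracks, gene-array segmentation, convergent/divergent/tandem
   junction classification, and the unspliced (intron-overlapping) read
   fraction as a nascent-transcription proxy.
4. **Correspondence** (`dinotad.correspondence`): boundary↔junction matching
   with a circular-shift permutation null, Hi-C and RNA metaplots around
   boundaries, and a boundary-strength scalar (intra-domain / cross-boundary
   mean O/E) compared across inhibition doses.
5. **Simulation** (`dinotad.simulate`): genomes in which every domain is a
   divergent pair of gene arrays (so convergent junctions sit exactly at
   domain boundaries), contact maps with intensity
   `λ_ij ∝ d^-α · [(1−m)·F_ij + m]` (F = block enrichment, m = decompaction
   mixing), spliced transcripts with embedded ORFs, and reads with a
   controlled nascent fraction.

## Worked example

```python
from dinotad import *
from dinotad.simulate import SimulationConfig, simulate_genome, simulate_contact_map

cfg = SimulationConfig()                      # 10 Mb, 50-kb bins, E=3, seed 1
genome, truth = simulate_genome(cfg)
cmap = mask_sparse_bins(simulate_contact_map(truth, cfg), min_marginal=1)
kr_balance(cmap)

boundaries = call_boundaries(tad_separation_score(cmap), cmap)
print(len(boundaries), len(truth.boundaries["chr1"]))   # -> 18 19

tracks = build_strand_tracks(truth.transcripts, truth.grid)
junctions = classify_junctions(segment_gene_arrays(tracks))
table = match_boundaries_to_junctions(boundaries, junctions, max_dist=50_000)
print(round(table["matched"].mean(), 3))                # -> 1.0
```

Of the 19 planted boundaries, 18 are recovered (the first lies too close to
the chromosome start for the largest scoring window) and every called
boundary falls within one bin of a convergent gene-array junction.

The same pipeline is scriptable from the shell:

```bash
dinotad simulate --seed 1 --outdir sim/
dinotad call-domains sim/contacts.coo.tsv sim/chrom.sizes --out-prefix sim/run
dinotad run-all --config my_config.json
```

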