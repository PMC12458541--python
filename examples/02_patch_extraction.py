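"""Extract cell-centered patches and rasterize them into dense tensors.

Each cell sits at the center of exactly one square patch; neighboring
patches may overlap, so one transcript can contribute context to several
patches.  The sparse store keeps (patch_id, gene_index, x_local, y_local);
densification at reduction r bins pixels into (G, S/r, S/r) count tensors.
"""

import zipaer as z
from zipaer.patchify import PatchConfig, densify_all

transcripts, cells, truth = z.simulate(z.SimConfig(seed=0))
vocab = z.GeneVocabulary(list(truth.gene_means["gene"]))

records = z.assign_transcripts_to_patches(transcripts, cells, patch_size_px=64,
                                          vocab=vocab)
store = z.SparsePatchStore(records)
print(f"{len(records)} patch records over {len(store.patch_ids)} patches "
      f"(from {len(transcripts)} transcripts; overlaps duplicate, "
      f"out-of-patch transcripts drop)")

config = PatchConfig(patch_size_px=64, reduction_r=2)
stack, ids = densify_all(store, config, vocab)
print(f"dense stack: {stack.shape}  (patches x genes x {config.side} x {config.side})")
print(f"transcript conservation: stack sum {stack.sum()} == records {len(records)}")
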