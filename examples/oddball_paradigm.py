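"""Generate an auditory emotional-oddball stimulus block.

One block holds 110 vocal stimuli: 86 neutral standards plus 12 happy and
12 sad deviants in randomly permuted order, with the constraint that two
rare (deviant) sounds never occur back to back."""

from dynconn import generate_block

block = generate_block(seed=3)
n_std, n_happy, n_sad = block.counts
print(f"block length {len(block.sequence)}: "
      f"{n_std} standards, {n_happy} happy, {n_sad} sad")
print("first 20 stimuli:", " ".join(
    {"standard": ".", "happy": "H", "sad": "S"}[s]
    for s in block.sequence[:20]), "(. = standard)")
adjacent = sum(a != "standard" and b != "standard"
               for a, b in zip(block.sequence, block.sequence[1:]))
print(f"adjacent deviant pairs: {adjacent} (constraint: 0)")
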