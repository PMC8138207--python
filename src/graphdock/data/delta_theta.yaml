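# Quantum-rotation-gate (QRGO) angle schedule.
#
# Keyed by (bit, best, better): the chromosome's measured bit, the best
# chromosome's bit at the same position, and whether the chromosome's
# fitness is >= the best fitness.  `magnitude` is |Δθ| in units of π.
# `target` names the bit value the rotation should make more probable
# ("best", "self", or "none" for no rotation); the sign of Δθ is derived
# from the current qubit amplitudes so the measurement probability moves
# toward the target (s(α,β) convention).
rows:
  - {bit: 0, best: 0, better: false, magnitude: 0.0,  target: none}
  - {bit: 0, best: 0, better: true,  magnitude: 0.0,  target: none}
  - {bit: 0, best: 1, better: false, magnitude: 0.05, target: best}
  - {bit: 0, best: 1, better: true,  magnitude: 0.01, target: self}
  - {bit: 1, best: 0, better: false, magnitude: 0.05, target: best}
  - {bit: 1, best: 0, better: true,  magnitude: 0.01, target: self}
  - {bit: 1, best: 1, better: false, magnitude: 0.0,  target: none}
  - {bit: 1, best: 1, better: true,  magnitude: 0.0,  target: none}
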