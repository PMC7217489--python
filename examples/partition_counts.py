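"""How the MIRAC search-space restrictions shrink the number of candidate
partitions: all set partitions (Bell number) -> contiguous partitions of a
leaf ordering (compositions, 2^(n-1)) -> compositions with every cluster
at least t cells."""

from scmirac import partition_counts

for n in (20, 60, 100):
    pc = partition_counts(n, t=20)
    print(f"n={n:4d}  bell={pc.bell:.3e}  compositions={pc.compositions:.3e}  "
          f"min-size-{pc.t} compositions={pc.compositions_min_t}")

print()
print("The last column is what MIRAC's merge sweep actually has to consider:")
print("23 candidate partitions at n=60 instead of ~10^59 set partitions.")
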