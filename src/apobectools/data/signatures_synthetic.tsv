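MutationType	SBS1	SBS2	SBS5	SBS13	SBS40
A[C>A]A	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
A[C>A]C	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
A[C>A]G	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
A[C>A]T	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
C[C>A]A	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
C[C>A]C	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
C[C>A]G	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
C[C>A]T	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
G[C>A]A	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
G[C>A]C	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
G[C>A]G	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
G[C>A]T	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
T[C>A]A	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
T[C>A]C	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
T[C>A]G	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
T[C>A]T	0.00200000	0.00100000	0.00375000	0.00100000	0.02062500
A[C>G]A	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
A[C>G]C	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
A[C>G]G	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
A[C>G]T	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
C[C>G]A	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
C[C>G]C	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
C[C>G]G	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
C[C>G]T	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
G[C>G]A	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
G[C>G]C	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
G[C>G]G	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
G[C>G]T	0.00200000	0.00100000	0.00187500	0.00100000	0.00375000
T[C>G]A	0.00200000	0.00100000	0.00187500	0.25100000	0.00375000
T[C>G]C	0.00200000	0.00100000	0.00187500	0.11100000	0.00375000
T[C>G]G	0.00200000	0.00100000	0.00187500	0.07100000	0.00375000
T[C>G]T	0.00200000	0.00100000	0.00187500	0.47500000	0.00375000
A[C>T]A	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
A[C>T]C	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
A[C>T]G	0.18200000	0.00100000	0.02187500	0.00100000	0.00750000
A[C>T]T	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
C[C>T]A	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
C[C>T]C	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
C[C>T]G	0.14200000	0.00100000	0.02187500	0.00100000	0.00750000
C[C>T]T	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
G[C>T]A	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
G[C>T]C	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
G[C>T]G	0.11200000	0.00100000	0.02187500	0.00100000	0.00750000
G[C>T]T	0.00200000	0.00100000	0.02187500	0.00100000	0.00750000
T[C>T]A	0.00200000	0.19100000	0.02187500	0.00100000	0.00750000
T[C>T]C	0.00200000	0.11100000	0.02187500	0.00100000	0.00750000
T[C>T]G	0.38000000	0.09100000	0.02187500	0.00100000	0.00750000
T[C>T]T	0.00200000	0.51500000	0.02187500	0.00100000	0.00750000
A[T>A]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
A[T>A]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
A[T>A]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
A[T>A]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
C[T>A]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
C[T>A]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
C[T>A]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
C[T>A]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
G[T>A]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
G[T>A]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
G[T>A]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
G[T>A]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
T[T>A]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
T[T>A]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
T[T>A]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
T[T>A]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00875000
A[T>C]A	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
A[T>C]C	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
A[T>C]G	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
A[T>C]T	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
C[T>C]A	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
C[T>C]C	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
C[T>C]G	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
C[T>C]T	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
G[T>C]A	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
G[T>C]C	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
G[T>C]G	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
G[T>C]T	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
T[T>C]A	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
T[T>C]C	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
T[T>C]G	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
T[T>C]T	0.00200000	0.00100000	0.02500000	0.00100000	0.01250000
A[T>G]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
A[T>G]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
A[T>G]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
A[T>G]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
C[T>G]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
C[T>G]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
C[T>G]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
C[T>G]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
G[T>G]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
G[T>G]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
G[T>G]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
G[T>G]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
T[T>G]A	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
T[T>G]C	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
T[T>G]G	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
T[T>G]T	0.00200000	0.00100000	0.00500000	0.00100000	0.00937500
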