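# Acceptor (3') splice-site base frequencies over the 23-mer window
# (20 intronic positions ending in AG, then 3 exonic).  Packaged default
# for the log-odds PWM scorer; reflects the polypyrimidine tract and the
# invariant AG of human acceptor sites.
position	A	C	G	T
-20	0.10	0.32	0.13	0.45
-19	0.10	0.32	0.13	0.45
-18	0.10	0.32	0.13	0.45
-17	0.10	0.32	0.13	0.45
-16	0.10	0.32	0.13	0.45
-15	0.10	0.32	0.13	0.45
-14	0.10	0.32	0.13	0.45
-13	0.10	0.32	0.13	0.45
-12	0.10	0.32	0.13	0.45
-11	0.10	0.32	0.13	0.45
-10	0.10	0.32	0.13	0.45
-9	0.10	0.32	0.13	0.45
-8	0.10	0.32	0.13	0.45
-7	0.10	0.32	0.13	0.45
-6	0.10	0.32	0.13	0.45
-5	0.10	0.32	0.13	0.45
-4	0.23	0.30	0.22	0.25
-3	0.07	0.65	0.03	0.25
-2	0.990	0.003	0.004	0.003
-1	0.003	0.003	0.990	0.004
1	0.25	0.12	0.52	0.11
2	0.28	0.22	0.25	0.25
3	0.25	0.25	0.25	0.25
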