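# Synthetic placeholder injection protocol: 31 (source, sink) electrode pairs
# among 32 scalp electrodes.  The published protocol is not reproduced here;
# these pairs are a documented stand-in chosen for diversity of electrode
# separation (16, 10, 6 and 3 positions around the ring).  Replace with the
# published protocol file when processing real recordings.
1 17
3 19
5 21
7 23
9 25
11 27
13 29
15 31
2 12
6 16
10 20
14 24
18 28
22 32
26 4
30 8
1 7
5 11
9 15
13 19
17 23
21 27
25 31
29 3
2 5
8 11
14 17
20 23
26 29
32 3
6 9
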