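>hOrai1 human Orai1 C-terminus, residues 260-301 of the full-length protein
SLVSHKTDRQFQELNELAEFARLQDQLDHRGDHPLTPGSHYA
>xOrai1 SYNTHETIC STAND-IN for the Xenopus Orai1 C-terminus (true accession sequence unavailable offline); hOrai1-derived with F279Y plus T266S/P295S, giving the strongest coiled coil of the three isoforms
SLVSHKSDRQFQELNELAEYARLQDQLDHRGDHPLTSGSHYA
>xOrai2 SYNTHETIC STAND-IN for the Xenopus Orai2 C-terminus (true accession sequence unavailable offline); diverged at F270W/L276T/A280S/D287G/G290S/H299N, giving the weakest coiled coil of the three isoforms
SLVSHKTDRQWQELNETAEFSRLQDQLGHRSDHPLTPGSNYA
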