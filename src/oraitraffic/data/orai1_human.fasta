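>hOrai1 human Orai1 full length, 301 aa, 1-based UniProt numbering; cytosolic C-terminus 260-301
MHPEPAPPPSRSSPELPPSGGSTTSGSRRSRRRSGDGEPPGAPPPPPSAVTYPDWIGQSY
SEVMSLNEHSMQALSWRKLYLSRAKLKASSRTSALLSGFAMVAMVEVQLDADHDYPPGLL
IAFSACTTVLVAVHLFALMISTCILPNIEAVSNVHNLNSVKESPHERMHRHIEMAWAFST
VIGTLLFLAEVVLLCWVKFLPLKKQPGQPRPTSKPPASGAAANVSTSGITPGQAAAIAST
TIMVPFGLIFIVLAVHFYRSLVSHKTDRQFQELNELAEFARLQDQLDHRGDHPLTPGSHY
A
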