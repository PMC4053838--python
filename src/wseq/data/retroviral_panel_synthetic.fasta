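>gag_like_1 synthetic retroviral-like toy protein
MGCIGTSKKAQGIKEGLAEEGQLLPNTMHTAARNPNYFIAEGLGAIDGPITMFAREQQKI
ISAIGVETRVSRVREYIKIGSRLGPSMVTGATRIWFIQGLQLSFTNKRDRKLRTIAQSAL
QCTTRQCVVPMIKLETKHPKNHGYHGKTAISLNFYRYSTHELGAIEDNSSLLPLVLREKT
>gag_like_2 synthetic retroviral-like toy protein
MCVGVVDQAEPTLLTVQHRQAKDIIPPRQRSNEAILFSKILDGPEYIVTSGSDWWPKYSR
EIIRGVAAPRKPRVEQISVVFYRTQGFLQAGPYKLIRDNKIRQPQYKYRNVHPRASKQLL
GTSLTHPSHFRVLQGRSSLQTTELLTIADV
>pol_like_1 synthetic retroviral-like toy protein
MCVPRSWKSDLSVGNDKVSRGKLEGDHKKIEAETLLWLEQRLILAEPPTLTEGYKNTINQ
RVSRLLATFSKSNENGVNQAAEASQVYSPFPPSRSVKRYAITLNANADKEPGSIVTIKMA
GLDRLQTGIDTSQIEIRAKEPERTQAEESSVIVRQWAPLKNAAVKETSLIIWQRRLSHVS
VLTLSAMTEGVEKLNQGRAGLTTLGEGLQEPPFGPSLSRRGPAGAVDTYEDKDTRKETGI
>pol_like_2 synthetic retroviral-like toy protein
MDDGADQYAYDAKLVIIVSAATLPAQSMSNAVWTLDICARFARMMALTILDKGPSVDHAP
KSCAIYSGLDTHGMDFWNGEHLYVLDIILTDETQLKKPVTQEVVGESYDYFGRDLECKVI
QKHSLTKQTLLGNQEMRKAGVELQLLTACHSLPSKGEGKTCGQKPKMIRSPSPPPNDTLT
DIAKLEVLMSIASKLPGPIERIVVVIVDSS
>env_like_1 synthetic retroviral-like toy protein
MMQSQGVSYDSYILPLGEYLLKEEKRIKDQIPGEVNEKDIHNIPDAFQGNGVVILGTLYE
DPEKALKSVESLDGHDISTYFLGKQSNKQAKGTAEHVVCKELKNKKLPFVANLRKLDIEE
IYGRKNATSS
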