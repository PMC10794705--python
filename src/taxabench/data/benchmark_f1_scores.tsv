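threshold_pct	organism	pipeline_id	f1
0	Achromobacter xylosoxidans	bioBakery3	0.857
0	Achromobacter xylosoxidans	bioBakery4	0.857
0	Achromobacter xylosoxidans	JAMS	0.857
0	Achromobacter xylosoxidans	WGSA2	0.889
0	Achromobacter xylosoxidans	Woltka	0.889
0	Acinetobacter baumannii	bioBakery3	0.857
0	Acinetobacter baumannii	bioBakery4	0.857
0	Acinetobacter baumannii	JAMS	0.857
0	Acinetobacter baumannii	WGSA2	0.889
0	Acinetobacter baumannii	Woltka	0.889
0	Aeromonas hydrophila	bioBakery3	0.889
0	Aeromonas hydrophila	bioBakery4	0.889
0	Aeromonas hydrophila	JAMS	0.889
0	Aeromonas hydrophila	WGSA2	1.000
0	Aeromonas hydrophila	Woltka	1.000
0	Enterococcus faecalis	bioBakery3	1.000
0	Enterococcus faecalis	bioBakery4	1.000
0	Enterococcus faecalis	JAMS	0.857
0	Enterococcus faecalis	WGSA2	0.889
0	Enterococcus faecalis	Woltka	0.889
0	Escherichia coli	bioBakery3	0.889
0	Escherichia coli	bioBakery4	0.889
0	Escherichia coli	JAMS	0.889
0	Escherichia coli	WGSA2	0.889
0	Escherichia coli	Woltka	0.889
0	Klebsiella pneumoniae	bioBakery3	0.857
0	Klebsiella pneumoniae	bioBakery4	0.857
0	Klebsiella pneumoniae	JAMS	1.000
0	Klebsiella pneumoniae	WGSA2	0.889
0	Klebsiella pneumoniae	Woltka	0.889
0	Legionella pneumophila	bioBakery3	1.000
0	Legionella pneumophila	bioBakery4	1.000
0	Legionella pneumophila	JAMS	1.000
0	Legionella pneumophila	WGSA2	1.000
0	Legionella pneumophila	Woltka	1.000
0	Listeria monocytogenes	bioBakery3	0.857
0	Listeria monocytogenes	bioBakery4	0.857
0	Listeria monocytogenes	JAMS	0.857
0	Listeria monocytogenes	WGSA2	0.889
0	Listeria monocytogenes	Woltka	0.889
0	Neisseria meningitidis	bioBakery3	0.857
0	Neisseria meningitidis	bioBakery4	0.857
0	Neisseria meningitidis	JAMS	0.857
0	Neisseria meningitidis	WGSA2	0.889
0	Neisseria meningitidis	Woltka	0.889
0	Salmonella enterica	bioBakery3	0.857
0	Salmonella enterica	bioBakery4	0.857
0	Salmonella enterica	JAMS	0.889
0	Salmonella enterica	WGSA2	0.889
0	Salmonella enterica	Woltka	0.889
0	Shigella sonnei	bioBakery3
0	Shigella sonnei	bioBakery4
0	Shigella sonnei	JAMS	1.000
0	Shigella sonnei	WGSA2	0.889
0	Shigella sonnei	Woltka	0.889
0	Staphylococcus aureus	bioBakery3	0.857
0	Staphylococcus aureus	bioBakery4	0.857
0	Staphylococcus aureus	JAMS	0.857
0	Staphylococcus aureus	WGSA2	0.889
0	Staphylococcus aureus	Woltka	0.889
0	Streptococcus pyogenes	bioBakery3	0.857
0	Streptococcus pyogenes	bioBakery4	0.857
0	Streptococcus pyogenes	JAMS	0.857
0	Streptococcus pyogenes	WGSA2	0.889
0	Streptococcus pyogenes	Woltka	0.889
0	Vibrio furnissii	bioBakery3	0.857
0	Vibrio furnissii	bioBakery4	0.857
0	Vibrio furnissii	JAMS	0.857
0	Vibrio furnissii	WGSA2	0.889
0	Vibrio furnissii	Woltka	0.889
0.01	Achromobacter xylosoxidans	bioBakery3	0.857
0.01	Achromobacter xylosoxidans	bioBakery4	0.857
0.01	Achromobacter xylosoxidans	JAMS	0.857
0.01	Achromobacter xylosoxidans	WGSA2	1.000
0.01	Achromobacter xylosoxidans	Woltka	1.000
0.01	Acinetobacter baumannii	bioBakery3	0.857
0.01	Acinetobacter baumannii	bioBakery4	0.857
0.01	Acinetobacter baumannii	JAMS	0.857
0.01	Acinetobacter baumannii	WGSA2	1.000
0.01	Acinetobacter baumannii	Woltka	1.000
0.01	Aeromonas hydrophila	bioBakery3	0.889
0.01	Aeromonas hydrophila	bioBakery4	0.889
0.01	Aeromonas hydrophila	JAMS
0.01	Aeromonas hydrophila	WGSA2	1.000
0.01	Aeromonas hydrophila	Woltka	1.000
0.01	Enterococcus faecalis	bioBakery3	0.857
0.01	Enterococcus faecalis	bioBakery4	1.000
0.01	Enterococcus faecalis	JAMS	0.857
0.01	Enterococcus faecalis	WGSA2	1.000
0.01	Enterococcus faecalis	Woltka	1.000
0.01	Escherichia coli	bioBakery3	0.889
0.01	Escherichia coli	bioBakery4	0.889
0.01	Escherichia coli	JAMS	0.889
0.01	Escherichia coli	WGSA2	0.889
0.01	Escherichia coli	Woltka	0.889
0.01	Klebsiella pneumoniae	bioBakery3	0.857
0.01	Klebsiella pneumoniae	bioBakery4	0.857
0.01	Klebsiella pneumoniae	JAMS	0.857
0.01	Klebsiella pneumoniae	WGSA2	1.000
0.01	Klebsiella pneumoniae	Woltka	0.889
0.01	Legionella pneumophila	bioBakery3	1.000
0.01	Legionella pneumophila	bioBakery4	1.000
0.01	Legionella pneumophila	JAMS	0.889
0.01	Legionella pneumophila	WGSA2	1.000
0.01	Legionella pneumophila	Woltka	1.000
0.01	Listeria monocytogenes	bioBakery3	0.857
0.01	Listeria monocytogenes	bioBakery4	0.857
0.01	Listeria monocytogenes	JAMS	0.857
0.01	Listeria monocytogenes	WGSA2	1.000
0.01	Listeria monocytogenes	Woltka	1.000
0.01	Neisseria meningitidis	bioBakery3	0.857
0.01	Neisseria meningitidis	bioBakery4	0.857
0.01	Neisseria meningitidis	JAMS	0.857
0.01	Neisseria meningitidis	WGSA2	1.000
0.01	Neisseria meningitidis	Woltka	1.000
0.01	Salmonella enterica	bioBakery3	0.857
0.01	Salmonella enterica	bioBakery4	0.750
0.01	Salmonella enterica	JAMS	0.889
0.01	Salmonella enterica	WGSA2	0.889
0.01	Salmonella enterica	Woltka	0.889
0.01	Shigella sonnei	bioBakery3
0.01	Shigella sonnei	bioBakery4
0.01	Shigella sonnei	JAMS	0.857
0.01	Shigella sonnei	WGSA2
0.01	Shigella sonnei	Woltka
0.01	Staphylococcus aureus	bioBakery3	0.857
0.01	Staphylococcus aureus	bioBakery4	0.857
0.01	Staphylococcus aureus	JAMS	0.857
0.01	Staphylococcus aureus	WGSA2	0.857
0.01	Staphylococcus aureus	Woltka	1.000
0.01	Streptococcus pyogenes	bioBakery3	0.857
0.01	Streptococcus pyogenes	bioBakery4	0.857
0.01	Streptococcus pyogenes	JAMS	0.857
0.01	Streptococcus pyogenes	WGSA2	1.000
0.01	Streptococcus pyogenes	Woltka	0.857
0.01	Vibrio furnissii	bioBakery3	0.857
0.01	Vibrio furnissii	bioBakery4	1.000
0.01	Vibrio furnissii	JAMS	0.857
0.01	Vibrio furnissii	WGSA2	1.000
0.01	Vibrio furnissii	Woltka
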