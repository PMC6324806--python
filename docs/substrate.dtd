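<!--
  Four-block substrate XML: the fixture contract for scissile.io_formats.

  One file describes one substrate peptide, the protease acting on it, and
  the product fragments ("metabolites") observed.  Chemical structure
  payloads (sdf/mol text) are opaque; the <sequence> token streams are
  authoritative for block identity.  For a hydrolysis metabolite,
  <cleaved-bond> is the 0-based index of the parent amide bond (bond i
  joins blocks i and i+1) and the complementary N- and C-terminal fragments
  both appear, each referencing the same bond.
-->
<!ELEMENT substrate (properties, parent, metabolized-parent, metabolites)>
<!ATTLIST substrate id CDATA #REQUIRED>

<!ELEMENT properties (matrix, peptidase-code, uniprot-acc, peptide-range,
                      organism, reference*)>
<!ELEMENT matrix (#PCDATA)>          <!-- protease name -->
<!ELEMENT peptidase-code (#PCDATA)>
<!ELEMENT uniprot-acc (#PCDATA)>
<!ELEMENT peptide-range (#PCDATA)>
<!ELEMENT organism (#PCDATA)>
<!ELEMENT reference (#PCDATA)>

<!ELEMENT parent (sequence, structure?, formula?, mz?)>
<!ELEMENT metabolized-parent (sequence?, structure?, formula?, mz?)>
<!ELEMENT sequence (#PCDATA)>        <!-- block tokens, e.g. AAD[Aib]GK -->
<!ELEMENT structure (#PCDATA)>       <!-- opaque sdf/mol payload -->
<!ELEMENT formula (#PCDATA)>
<!ELEMENT mz (#PCDATA)>

<!ELEMENT metabolites (metabolite*)>
<!ELEMENT metabolite (name, sequence, mechanism, cleaved-bond?, count,
                      structure?)>
<!ELEMENT name (#PCDATA)>
<!ELEMENT mechanism (#PCDATA)>       <!-- "hydrolysis" for cleavage -->
<!ELEMENT cleaved-bond (#PCDATA)>    <!-- 0-based parent bond index -->
<!ELEMENT count (#PCDATA)>           <!-- independent observations -->
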